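"""Dataset assembly: length filtering, identity de-redundancy, similarity purge.

The pipeline mirrors standard curation practice for sequence classifiers:

1. keep sequences of 50-2000 residues (the size range of proteins expressible
   in transgenic plants),
2. collapse the positive set to cluster representatives at 70% pairwise
   identity to avoid redundancy-driven overfitting,
3. remove negatives with significant local-alignment similarity to any
   positive (E <= 0.01), so the negative set carries no hidden positives.

Pairwise identity uses global (Needleman-Wunsch) alignment with BLOSUM62,
gap open 10 / extend 1; identity = identical columns / alignment length
including gap columns. The purge uses Smith-Waterman scores converted to
E-values with the Karlin-Altschul approximation for gapped BLOSUM62.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from .io import SequenceRecord

# Gapped BLOSUM62 Karlin-Altschul parameters (open 11 / extend 1 regime),
# used as an approximation for converting raw Smith-Waterman scores.
KA_LAMBDA = 0.267
KA_K = 0.041


@dataclass
class CurationConfig:
    min_length: int = 50
    max_length: int = 2000
    cluster_identity: float = 0.70
    purge_evalue: float = 0.01
    substitution_matrix: str = "BLOSUM62"
    gap_open: float = 10.0
    gap_extend: float = 1.0

    def __post_init__(self) -> None:
        if not (0 < self.min_length <= self.max_length):
            raise ValueError("need 0 < min_length <= max_length")
        if not (0 < self.cluster_identity <= 1):
            raise ValueError("cluster_identity must be in (0, 1]")
        if self.purge_evalue <= 0:
            raise ValueError("purge_evalue must be positive")


@dataclass
class AuditEntry:
    record_id: str
    step: str
    action: str
    detail: str


@dataclass
class CuratedDataset:
    positives: list[SequenceRecord]
    negatives: list[SequenceRecord]
    provenance: list[AuditEntry] = field(default_factory=list)

    def audit_tsv(self) -> str:
        lines = ["id\tstep\taction\tdetail"]
        lines += [f"{e.record_id}\t{e.step}\t{e.action}\t{e.detail}" for e in self.provenance]
        return "\n".join(lines) + "\n"


# BLOSUM62 lacks J/O/U; substitute the standard stand-ins before aligning.
_ALIGN_SUBSTITUTIONS = str.maketrans({"J": "L", "O": "K", "U": "C"})


def _alignable(seq: str) -> str:
    return seq.translate(_ALIGN_SUBSTITUTIONS)


def _make_aligner(config: CurationConfig, mode: str) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    aligner.substitution_matrix = substitution_matrices.load(config.substitution_matrix)
    aligner.open_gap_score = -config.gap_open
    aligner.extend_gap_score = -config.gap_extend
    return aligner


def filter_by_length(
    records: Sequence[SequenceRecord],
    min_length: int = 50,
    max_length: int = 2000,
) -> list[SequenceRecord]:
    """Retain records with min_length <= len <= max_length (inclusive)."""
    return [r for r in records if min_length <= len(r) <= max_length]


def pairwise_identity(
    a: SequenceRecord,
    b: SequenceRecord,
    config: Optional[CurationConfig] = None,
) -> float:
    """Global-alignment identity between two records, in [0, 1].

    Identity is identical aligned columns divided by total alignment length
    (gap columns included). Symmetric; 1.0 for identical sequences.
    """
    config = config or CurationConfig()
    aligner = _make_aligner(config, "global")
    alignment = aligner.align(_alignable(a.sequence), _alignable(b.sequence))[0]
    counts = alignment.counts()
    length = counts.gaps + counts.identities + counts.mismatches
    return counts.identities / length


def cluster_by_identity(
    records: Sequence[SequenceRecord],
    threshold: float = 0.70,
    config: Optional[CurationConfig] = None,
) -> tuple[list[SequenceRecord], dict[str, str]]:
    """Greedy incremental clustering, longest sequence first (CD-HIT style).

    Each record, visited in order of decreasing length (ties by id), either
    joins the first existing representative with identity >= threshold or
    founds a new cluster. Returns (representatives, id -> representative id);
    representatives map to themselves.
    """
    config = config or CurationConfig()
    ordered = sorted(records, key=lambda r: (-len(r), r.id))
    representatives: list[SequenceRecord] = []
    assignment: dict[str, str] = {}
    for rec in ordered:
        for rep in representatives:
            if pairwise_identity(rec, rep, config) >= threshold:
                assignment[rec.id] = rep.id
                break
        else:
            representatives.append(rec)
            assignment[rec.id] = rec.id
    # preserve original input order among representatives
    rep_ids = {r.id for r in representatives}
    reps_in_order = [r for r in records if r.id in rep_ids]
    return reps_in_order, assignment


def local_alignment_evalue(
    query: SequenceRecord,
    subject: SequenceRecord,
    config: Optional[CurationConfig] = None,
) -> tuple[float, float]:
    """Smith-Waterman score and Karlin-Altschul E-value for a sequence pair.

    E = K * m * n * exp(-lambda * S), with m, n the sequence lengths. This is
    an approximation calibrated for gapped BLOSUM62 scoring.
    """
    config = config or CurationConfig()
    aligner = _make_aligner(config, "local")
    score = aligner.score(_alignable(query.sequence), _alignable(subject.sequence))
    evalue = KA_K * len(query) * len(subject) * math.exp(-KA_LAMBDA * score)
    return score, evalue


def purge_positive_like(
    negatives: Sequence[SequenceRecord],
    positives: Sequence[SequenceRecord],
    config: Optional[CurationConfig] = None,
    audit: Optional[list[AuditEntry]] = None,
) -> list[SequenceRecord]:
    """Remove negatives with a significant local-alignment hit to any positive.

    A negative is purged when its best hit against the positive set has
    E-value <= config.purge_evalue. Order of retained negatives is preserved.
    """
    config = config or CurationConfig()
    kept: list[SequenceRecord] = []
    for neg in negatives:
        best: Optional[tuple[float, float, str]] = None  # (evalue, score, pos id)
        for pos in positives:
            score, evalue = local_alignment_evalue(neg, pos, config)
            if best is None or evalue < best[0]:
                best = (evalue, score, pos.id)
        assert best is not None
        if best[0] <= config.purge_evalue:
            if audit is not None:
                audit.append(
                    AuditEntry(
                        neg.id,
                        "purge_positive_like",
                        "removed",
                        f"best hit {best[2]} score={best[1]:.1f} E={best[0]:.3g}",
                    )
                )
        else:
            kept.append(neg)
    return kept


def assemble_dataset(
    positives: Sequence[SequenceRecord],
    negatives: Sequence[SequenceRecord],
    config: Optional[CurationConfig] = None,
) -> CuratedDataset:
    """Apply the full curation pipeline and return the dataset with audit trail.

    Length-filters both sets, clusters the positives at the identity
    threshold (representatives kept), and purges positive-like negatives.
    """
    config = config or CurationConfig()
    audit: list[AuditEntry] = []

    def _length_step(records: Sequence[SequenceRecord], side: str) -> list[SequenceRecord]:
        kept = filter_by_length(records, config.min_length, config.max_length)
        kept_ids = {r.id for r in kept}
        for r in records:
            if r.id not in kept_ids:
                audit.append(
                    AuditEntry(r.id, "filter_by_length", "removed", f"length={len(r)}")
                )
        return kept

    pos = _length_step(positives, "positive")
    neg = _length_step(negatives, "negative")
    if not pos:
        raise ValueError("no positive sequences remain after length filtering")
    if not neg:
        raise ValueError("no negative sequences remain after length filtering")

    reps, assignment = cluster_by_identity(pos, config.cluster_identity, config)
    rep_ids = {r.id for r in reps}
    for r in pos:
        if r.id not in rep_ids:
            audit.append(
                AuditEntry(
                    r.id, "cluster_by_identity", "removed",
                    f"assigned to representative {assignment[r.id]}",
                )
            )
    neg = purge_positive_like(neg, reps, config, audit)
    if not neg:
        raise ValueError("no negative sequences remain after similarity purge")

    pos_ids = {r.id for r in reps}
    if pos_ids & {r.id for r in neg}:
        raise ValueError("positive and negative ids overlap")
    return CuratedDataset(positives=reps, negatives=neg, provenance=audit)
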