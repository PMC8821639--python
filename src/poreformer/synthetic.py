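"""Synthetic benchmark sequences with controllable pore-former-like signal.

The generator emulates the structure of a pore-former training set without
any claim to real membrane-protein biophysics: positives are background
chains carrying (a) short family-specific sequence motifs and (b) a global
composition shift toward hydrophobic residues, both scaled by a single
``signal_strength`` knob. At ``signal_strength = 0`` positives are
distributionally identical to the background. A "novel" holdout family
shares the hydrophobic bias but uses motifs disjoint from every training
family — the same-physics / different-sequence scenario that a homology
search cannot bridge.

All generation is deterministic per seed; each component draws from its own
seeded stream so that, e.g., adding a family does not perturb the negatives.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np

from .alphabet import CANONICAL_RESIDUES
from .curation import CuratedDataset
from .io import Label, SequenceRecord, write_fasta

HYDROPHOBIC_RESIDUES = "AILMFVWC"

MOTIF_LENGTH_RANGE = (8, 15)


@dataclass
class FamilySpec:
    """One synthetic positive family: a named motif set plus bias strength."""

    name: str
    motifs: tuple[str, ...]
    n_motifs_per_seq: int = 3
    bias_weight: float = 0.3  # max fraction of composition pulled hydrophobic
    strength_scale: float = 1.0  # per-family multiplier on signal_strength

    def __post_init__(self) -> None:
        for m in self.motifs:
            if not m or any(c not in CANONICAL_RESIDUES for c in m):
                raise ValueError(f"motif {m!r} must use canonical residues only")


@dataclass
class SyntheticConfig:
    n_per_family: int = 100
    n_negatives: int = 200
    n_holdout: int = 50
    min_length: int = 100
    max_length: int = 400
    background_composition: Optional[np.ndarray] = None  # len 20, sums to 1
    signal_strength: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.signal_strength <= 1):
            raise ValueError("signal_strength must be in [0, 1]")
        if not (50 <= self.min_length <= self.max_length <= 2000):
            raise ValueError("length window must sit inside [50, 2000]")
        if self.background_composition is None:
            self.background_composition = np.full(20, 1 / 20)
        comp = np.asarray(self.background_composition, dtype=float)
        if comp.shape != (20,) or not np.isclose(comp.sum(), 1.0):
            raise ValueError("composition must be 20 frequencies summing to 1")
        self.background_composition = comp


def _stream(config: SyntheticConfig, name: str) -> np.random.Generator:
    """Independent deterministic stream per (seed, component name)."""
    return np.random.default_rng([config.seed, zlib.crc32(name.encode())])


def _biased_composition(config: SyntheticConfig, spec: FamilySpec) -> np.ndarray:
    base = config.background_composition
    hydro = np.array([1.0 if r in HYDROPHOBIC_RESIDUES else 0.0 for r in CANONICAL_RESIDUES])
    hydro /= hydro.sum()
    w = spec.bias_weight * config.signal_strength * spec.strength_scale
    return (1 - w) * base + w * hydro


def _random_chain(rng: np.random.Generator, length: int, comp: np.ndarray) -> list[str]:
    return list(rng.choice(list(CANONICAL_RESIDUES), size=length, p=comp))


def _plant_motifs(rng: np.random.Generator, chain: list[str],
                  motifs: Sequence[str], n_insert: int) -> list[str]:
    """Overwrite n_insert non-overlapping stretches with motifs from the set."""
    length = len(chain)
    occupied: list[tuple[int, int]] = []
    for _ in range(n_insert):
        motif = motifs[rng.integers(len(motifs))]
        if len(motif) > length:
            raise ValueError(f"motif {motif!r} longer than sequence length {length}")
        for _attempt in range(100):
            start = int(rng.integers(0, length - len(motif) + 1))
            span = (start, start + len(motif))
            if all(span[1] <= s or span[0] >= e for s, e in occupied):
                occupied.append(span)
                chain[span[0] : span[1]] = list(motif)
                break
    return chain


def random_motifs(rng: np.random.Generator, n: int) -> tuple[str, ...]:
    """Draw n random motifs of 8-15 canonical residues."""
    out = []
    for _ in range(n):
        k = int(rng.integers(MOTIF_LENGTH_RANGE[0], MOTIF_LENGTH_RANGE[1] + 1))
        out.append("".join(rng.choice(list(CANONICAL_RESIDUES), size=k)))
    return tuple(out)


def default_family_specs(seed: int = 0) -> list[FamilySpec]:
    """Two training pseudo-families sharing the hydrophobic bias but with
    disjoint motif sets (alpha / beta analogue)."""
    rng = np.random.default_rng([seed, zlib.crc32(b"family-motifs")])
    return [
        FamilySpec(name="alpha", motifs=random_motifs(rng, 3)),
        FamilySpec(name="beta", motifs=random_motifs(rng, 3)),
    ]


def generate_background(config: SyntheticConfig,
                        n: Optional[int] = None) -> list[SequenceRecord]:
    """I.i.d. background sequences (the diverse negative set)."""
    rng = _stream(config, "background")
    n = config.n_negatives if n is None else n
    records = []
    for i in range(n):
        length = int(rng.integers(config.min_length, config.max_length + 1))
        seq = "".join(_random_chain(rng, length, config.background_composition))
        records.append(SequenceRecord(f"neg_{i:04d}", seq, Label.NEGATIVE))
    return records


def generate_family(config: SyntheticConfig, spec: FamilySpec,
                    n: Optional[int] = None) -> list[SequenceRecord]:
    """Positive sequences for one family: biased composition + planted motifs."""
    rng = _stream(config, f"family:{spec.name}")
    comp = _biased_composition(config, spec)
    strength = config.signal_strength * spec.strength_scale
    n_insert = int(round(strength * spec.n_motifs_per_seq))
    n = config.n_per_family if n is None else n
    records = []
    for i in range(n):
        length = int(rng.integers(config.min_length, config.max_length + 1))
        chain = _random_chain(rng, length, comp)
        chain = _plant_motifs(rng, chain, spec.motifs, n_insert)
        records.append(
            SequenceRecord(f"{spec.name}_{i:04d}", "".join(chain),
                           Label.POSITIVE, family=spec.name)
        )
    return records


def generate_novel_family(
    config: SyntheticConfig,
    training_specs: Sequence[FamilySpec],
    name: str = "novel",
    n: Optional[int] = None,
) -> tuple[list[SequenceRecord], FamilySpec]:
    """A holdout family with the same hydrophobic bias but motifs disjoint
    from every training family (verified by exact string comparison)."""
    rng = _stream(config, f"novel:{name}")
    training_motifs = {m for spec in training_specs for m in spec.motifs}
    for _attempt in range(100):
        motifs = random_motifs(rng, 3)
        if not (set(motifs) & training_motifs):
            break
    else:
        raise ValueError("could not draw motifs disjoint from training specs")
    spec = FamilySpec(name=name, motifs=motifs)
    if set(spec.motifs) & training_motifs:
        raise ValueError("novel-family motifs collide with training motifs")
    records = generate_family(config, spec, n=config.n_holdout if n is None else n)
    return records, spec


def make_benchmark(
    config: Optional[SyntheticConfig] = None,
    family_specs: Optional[Sequence[FamilySpec]] = None,
    out_dir: Optional[str | Path] = None,
) -> tuple[CuratedDataset, list[SequenceRecord], dict]:
    """Build the full benchmark: two positive families, background negatives,
    and a motif-disjoint novel holdout family.

    Lengths and id-disjointness hold by construction, so the alignment-based
    curation steps are not re-run here. Returns (dataset, holdout, manifest);
    with *out_dir*, writes FASTA files plus a JSON manifest whose checksums
    make regeneration verifiable.
    """
    config = config or SyntheticConfig()
    specs = list(family_specs) if family_specs is not None else default_family_specs(config.seed)
    positives: list[SequenceRecord] = []
    for spec in specs:
        positives.extend(generate_family(config, spec))
    negatives = generate_background(config)
    holdout, novel_spec = generate_novel_family(config, specs)
    dataset = CuratedDataset(positives=positives, negatives=negatives)

    def _checksum(records: Sequence[SequenceRecord]) -> str:
        h = hashlib.sha256()
        for r in records:
            h.update(f">{r.id}\n{r.sequence}\n".encode())
        return h.hexdigest()

    manifest = {
        "seed": config.seed,
        "signal_strength": config.signal_strength,
        "n_per_family": config.n_per_family,
        "n_negatives": config.n_negatives,
        "n_holdout": config.n_holdout,
        "length_range": [config.min_length, config.max_length],
        "families": [
            {"name": s.name, "motifs": list(s.motifs),
             "n_motifs_per_seq": s.n_motifs_per_seq,
             "bias_weight": s.bias_weight,
             "strength_scale": s.strength_scale}
            for s in specs
        ],
        "novel_family": {"name": novel_spec.name, "motifs": list(novel_spec.motifs)},
        "checksums": {
            "positives": _checksum(positives),
            "negatives": _checksum(negatives),
            "holdout": _checksum(holdout),
        },
    }
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        for spec in specs:
            write_fasta([r for r in positives if r.family == spec.name],
                        out_dir / f"{spec.name}.fa")
        write_fasta(negatives, out_dir / "negatives.fa")
        write_fasta(holdout, out_dir / "holdout.fa")
        (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return dataset, holdout, manifest
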