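"""Curation rules: length window, identity clustering, similarity purge.

The independent oracle for alignment scoring is a brute-force Gotoh
(three-state affine) dynamic program written here, sharing nothing with the
implementation path except the published BLOSUM62 matrix values.
"""

import numpy as np
import pytest
from Bio.Align import substitution_matrices

from poreformer import (
    CurationConfig,
    SequenceRecord,
    assemble_dataset,
    cluster_by_identity,
    filter_by_length,
    pairwise_identity,
    purge_positive_like,
)
from poreformer.alphabet import CANONICAL_RESIDUES
from poreformer.curation import local_alignment_evalue

BLOSUM62 = substitution_matrices.load("BLOSUM62")
NEG_INF = float("-inf")


def gotoh_global_score(a: str, b: str, open_=10.0, ext=1.0) -> float:
    """Brute-force affine-gap global alignment score (end gaps penalized)."""
    n, m = len(a), len(b)
    M = np.full((n + 1, m + 1), NEG_INF)
    Ix = np.full((n + 1, m + 1), NEG_INF)  # gap in b
    Iy = np.full((n + 1, m + 1), NEG_INF)  # gap in a
    M[0, 0] = 0.0
    for i in range(1, n + 1):
        Ix[i, 0] = -(open_ + (i - 1) * ext)
    for j in range(1, m + 1):
        Iy[0, j] = -(open_ + (j - 1) * ext)
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = BLOSUM62[a[i - 1], b[j - 1]]
            M[i, j] = s + max(M[i - 1, j - 1], Ix[i - 1, j - 1], Iy[i - 1, j - 1])
            Ix[i, j] = max(M[i - 1, j] - open_, Ix[i - 1, j] - ext,
                           Iy[i - 1, j] - open_)
            Iy[i, j] = max(M[i, j - 1] - open_, Iy[i, j - 1] - ext,
                           Ix[i, j - 1] - open_)
    return max(M[n, m], Ix[n, m], Iy[n, m])


def _random_seq(rng, length):
    return "".join(rng.choice(list(CANONICAL_RESIDUES), size=length))


def _rec(i, seq, **kw):
    return SequenceRecord(f"s{i}", seq, **kw)


class TestFilterByLength:
    def test_boundaries_inclusive(self):
        records = [SequenceRecord(f"r{n}", "A" * n) for n in (49, 50, 2000, 2001)]
        kept = filter_by_length(records, 50, 2000)
        assert sorted(len(r) for r in kept) == [50, 2000]

    def test_empty_input_and_identity_case(self):
        assert filter_by_length([], 50, 2000) == []
        inside = [SequenceRecord("a", "A" * 100), SequenceRecord("b", "A" * 60)]
        assert filter_by_length(inside, 50, 2000) == inside

    def test_idempotent(self):
        records = [SequenceRecord(f"r{n}", "A" * n) for n in range(40, 70)]
        once = filter_by_length(records, 50, 60)
        assert filter_by_length(once, 50, 60) == once


class TestPairwiseIdentity:
    def test_identical_and_disjoint(self):
        assert pairwise_identity(_rec(1, "AAAA"), _rec(2, "AAAA")) == 1.0
        assert pairwise_identity(_rec(1, "AAAA"), _rec(2, "CCCC")) == 0.0

    def test_single_substitution(self):
        # L->I is a high-scoring substitution; the gapless alignment is optimal
        assert pairwise_identity(_rec(1, "MKVLA"), _rec(2, "MKVIA")) == pytest.approx(4 / 5)

    def test_symmetry_and_self_identity(self):
        rng = np.random.default_rng(11)
        for _ in range(5):
            a = _rec(1, _random_seq(rng, int(rng.integers(20, 50))))
            b = _rec(2, _random_seq(rng, int(rng.integers(20, 50))))
            assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))
            assert pairwise_identity(a, a) == 1.0

    def test_alignment_score_matches_gotoh_oracle(self):
        """The aligner's optimal global score equals the brute-force DP."""
        from Bio import Align

        config = CurationConfig()
        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.substitution_matrix = BLOSUM62
        aligner.open_gap_score = -config.gap_open
        aligner.extend_gap_score = -config.gap_extend
        rng = np.random.default_rng(7)
        for _ in range(15):
            a = _random_seq(rng, int(rng.integers(5, 50)))
            b = _random_seq(rng, int(rng.integers(5, 50)))
            assert aligner.score(a, b) == pytest.approx(gotoh_global_score(a, b))

    def test_substitution_only_pairs_match_hamming_identity(self):
        """With gap open 10, few-substitution pairs align gaplessly, so
        identity must equal matching positions / length."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            length = int(rng.integers(30, 51))
            seq = _random_seq(rng, length)
            mutant = list(seq)
            sites = rng.choice(length, size=3, replace=False)
            for site in sites:
                mutant[site] = "W" if seq[site] != "W" else "F"
            mutant = "".join(mutant)
            matches = sum(x == y for x, y in zip(seq, mutant))
            assert pairwise_identity(_rec(1, seq), _rec(2, mutant)) == pytest.approx(
                matches / length
            )


class TestClusterByIdentity:
    def test_identical_sequences_collapse(self):
        records = [SequenceRecord(f"r{i}", "MKVLAWIGHTY" * 4) for i in range(5)]
        reps, assignment = cluster_by_identity(records, 0.70)
        assert len(reps) == 1
        assert set(assignment.values()) == {reps[0].id}

    def test_dissimilar_sequences_stay_apart(self):
        rng = np.random.default_rng(5)
        records = [_rec(i, _random_seq(rng, 60)) for i in range(3)]
        # confirm the premise: all pairs below threshold
        for i in range(3):
            for j in range(i + 1, 3):
                assert pairwise_identity(records[i], records[j]) < 0.70
        reps, assignment = cluster_by_identity(records, 0.70)
        assert len(reps) == 3
        assert all(assignment[r.id] == r.id for r in records)

    def test_greedy_definition_holds_on_mixed_set(self):
        """Re-verify the longest-first greedy constraints pair by pair."""
        rng = np.random.default_rng(13)
        bases = [_random_seq(rng, int(n)) for n in (60, 55, 50)]
        records = []
        i = 0
        for base in bases:
            records.append(_rec(i := i + 1, base))
            for _ in range(2):  # near-duplicates: 4 substitutions, >= 90% identity
                variant = list(base)
                for site in rng.choice(len(base), size=4, replace=False):
                    variant[site] = "A" if base[site] != "A" else "G"
                records.append(_rec(i := i + 1, "".join(variant)))
        records.append(_rec(i := i + 1, _random_seq(rng, 45)))
        reps, assignment = cluster_by_identity(records, 0.70)

        order = sorted(records, key=lambda r: (-len(r), r.id))
        rep_order = [r for r in order if assignment[r.id] == r.id]
        rep_rank = {r.id: k for k, r in enumerate(rep_order)}
        by_id = {r.id: r for r in records}
        for rec in order:
            rep = by_id[assignment[rec.id]]
            if rec.id == rep.id:
                # a new representative is < threshold to all earlier ones
                for earlier in rep_order[: rep_rank[rec.id]]:
                    if len(earlier) >= len(rec):  # processed before rec
                        assert pairwise_identity(rec, earlier) < 0.70
            else:
                assert pairwise_identity(rec, rep) >= 0.70
                # and it joined the FIRST qualifying representative
                for earlier in rep_order[: rep_rank[rep.id]]:
                    assert pairwise_identity(rec, earlier) < 0.70
        assert {r.id for r in reps} == {r.id for r in rep_order}


class TestPurgePositiveLike:
    def test_identical_negative_removed(self):
        pos = [_rec(1, "MKVLAWIGHTYDERPINQCS" * 5)]
        neg = [SequenceRecord("n1", pos[0].sequence)]
        assert purge_positive_like(neg, pos) == []

    def test_unrelated_negative_retained(self):
        rng = np.random.default_rng(21)
        pos = [_rec(1, _random_seq(rng, 150))]
        neg = [SequenceRecord("n1", _random_seq(rng, 150))]
        assert purge_positive_like(neg, pos) == neg

    def test_planted_segment_purged_and_shuffled_control_retained(self):
        """A 60-residue verbatim copy of a positive segment is significant;
        the same residues shuffled are not."""
        rng = np.random.default_rng(42)
        pos = [_rec(1, _random_seq(rng, 200))]
        segment = pos[0].sequence[50:110]
        backbone = _random_seq(rng, 200)
        planted = backbone[:70] + segment + backbone[130:]
        shuffled_seg = "".join(rng.permutation(list(segment)))
        control = backbone[:70] + shuffled_seg + backbone[130:]
        neg = [SequenceRecord("planted", planted), SequenceRecord("control", control)]

        kept = purge_positive_like(neg, pos)
        assert [r.id for r in kept] == ["control"]
        # the Smith-Waterman score gap drives the decision
        s_planted, e_planted = local_alignment_evalue(neg[0], pos[0])
        s_control, e_control = local_alignment_evalue(neg[1], pos[0])
        assert s_planted > s_control
        assert e_planted <= 0.01 < e_control


class TestAssembleDataset:
    def _toy_sets(self):
        rng = np.random.default_rng(8)
        base = _random_seq(rng, 80)
        near = list(base)
        for site in rng.choice(80, size=5, replace=False):
            near[site] = "A" if base[site] != "A" else "G"
        positives = [
            SequenceRecord("p1", base, "positive", family="alpha"),
            SequenceRecord("p2", "".join(near), "positive", family="alpha"),
            SequenceRecord("p3", _random_seq(rng, 90), "positive", family="beta"),
            SequenceRecord("p_short", _random_seq(rng, 30), "positive"),
        ]
        negatives = [
            SequenceRecord("n1", _random_seq(rng, 100), "negative"),
            SequenceRecord("n_like", base, "negative"),
            SequenceRecord("n_long", _random_seq(rng, 150), "negative"),
        ]
        return positives, negatives

    def test_composition_equals_stepwise_application(self):
        positives, negatives = self._toy_sets()
        config = CurationConfig(min_length=50, max_length=120)
        dataset = assemble_dataset(positives, negatives, config)

        pos_f = filter_by_length(positives, 50, 120)
        neg_f = filter_by_length(negatives, 50, 120)
        reps, _ = cluster_by_identity(pos_f, config.cluster_identity, config)
        neg_purged = purge_positive_like(neg_f, reps, config)
        assert [r.id for r in dataset.positives] == [r.id for r in reps]
        assert [r.id for r in dataset.negatives] == [r.id for r in neg_purged]
        assert {e.record_id for e in dataset.provenance} >= {"p_short", "n_like"}

    def test_all_identical_positives_collapse_to_one(self):
        seq = "MKVLAWIGHTYDERPINQCS" * 5
        positives = [SequenceRecord(f"p{i}", seq, "positive") for i in range(4)]
        rng = np.random.default_rng(2)
        negatives = [SequenceRecord("n1", _random_seq(rng, 100), "negative")]
        dataset = assemble_dataset(positives, negatives)
        assert len(dataset.positives) == 1

    def test_full_identity_threshold_only_collapses_duplicates(self):
        rng = np.random.default_rng(9)
        base = _random_seq(rng, 80)
        near = "A" + base[1:] if base[0] != "A" else "G" + base[1:]
        positives = [
            SequenceRecord("p1", base, "positive"),
            SequenceRecord("p2", base, "positive"),       # exact duplicate
            SequenceRecord("p3", near, "positive"),        # 1 substitution
        ]
        negatives = [SequenceRecord("n1", _random_seq(rng, 100), "negative")]
        config = CurationConfig(cluster_identity=1.0)
        dataset = assemble_dataset(positives, negatives, config)
        assert sorted(r.id for r in dataset.positives) == ["p1", "p3"]

    def test_empty_sides_error(self):
        rng = np.random.default_rng(4)
        ok = [SequenceRecord("p1", _random_seq(rng, 100), "positive")]
        short = [SequenceRecord("n1", _random_seq(rng, 10), "negative")]
        with pytest.raises(ValueError):
            assemble_dataset(short, ok)
        with pytest.raises(ValueError):
            assemble_dataset(ok, short)
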