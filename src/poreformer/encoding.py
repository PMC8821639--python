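"""Per-residue numeric encodings of protein sequences.

Three schemes are supported, all producing a fixed-length matrix of shape
(pad_length, channels):

* ``one_hot``  — 28 channels, one indicator per alphabet symbol; padding
  positions light the dedicated pad channel.
* ``atchley``  — 5 channels, the Atchley physicochemical factor scores
  (polarity/accessibility, secondary-structure propensity, molecular size,
  codon composition, electrostatic charge); padding rows are all-zero.
* ``combined`` — 33 channels, columnwise concatenation of the two.

Ambiguity codes under the Atchley scheme follow standard semantics:
B = mean(D, N), Z = mean(E, Q), J = mean(I, L), X = mean of all twenty,
U takes the values of C, O the values of K, and ``*`` is all-zero.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .alphabet import CANONICAL_RESIDUES, DEFAULT_ALPHABET, ResidueAlphabet
from .io import Label, SequenceRecord

SCHEMES = ("one_hot", "atchley", "combined")

N_ONE_HOT_CHANNELS = 28
N_ATCHLEY_FACTORS = 5


class AtchleyTable:
    """Lookup of the five Atchley factor scores per canonical residue.

    Loaded from the TSV file shipped with the package; extended to the
    ambiguity codes via the substitution policy in the module docstring.
    """

    def __init__(self, factors: dict[str, np.ndarray]):
        if set(factors) != set(CANONICAL_RESIDUES):
            raise ValueError("table must cover exactly the 20 canonical residues")
        for res, vec in factors.items():
            vec = np.asarray(vec, dtype=float)
            if vec.shape != (N_ATCHLEY_FACTORS,) or not np.all(np.isfinite(vec)):
                raise ValueError(f"residue {res!r}: need 5 finite factor values")
            factors[res] = vec
        self._canonical = factors
        self._full = dict(factors)
        mean = lambda *rs: np.mean([factors[r] for r in rs], axis=0)
        self._full["B"] = mean("D", "N")
        self._full["Z"] = mean("E", "Q")
        self._full["J"] = mean("I", "L")
        self._full["X"] = mean(*CANONICAL_RESIDUES)
        self._full["U"] = factors["C"].copy()
        self._full["O"] = factors["K"].copy()
        self._full["*"] = np.zeros(N_ATCHLEY_FACTORS)

    @classmethod
    def load(cls) -> "AtchleyTable":
        ref = resources.files("poreformer.data").joinpath("atchley_factors.tsv")
        with resources.as_file(ref) as path:
            df = pd.read_csv(path, sep="\t", index_col="residue")
        return cls({res: row.to_numpy(dtype=float) for res, row in df.iterrows()})

    def __getitem__(self, residue: str) -> np.ndarray:
        return self._full[residue]

    @property
    def canonical(self) -> dict[str, np.ndarray]:
        return dict(self._canonical)


_DEFAULT_TABLE: Optional[AtchleyTable] = None


def default_atchley_table() -> AtchleyTable:
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = AtchleyTable.load()
    return _DEFAULT_TABLE


@dataclass
class EncodingConfig:
    scheme: str = "combined"
    pad_length: int = 2000
    alphabet: ResidueAlphabet = DEFAULT_ALPHABET

    def __post_init__(self) -> None:
        if self.scheme not in SCHEMES:
            raise ValueError(f"scheme must be one of {SCHEMES}, got {self.scheme!r}")
        if self.pad_length < 1:
            raise ValueError("pad_length must be positive")

    @property
    def channels(self) -> int:
        return {
            "one_hot": N_ONE_HOT_CHANNELS,
            "atchley": N_ATCHLEY_FACTORS,
            "combined": N_ONE_HOT_CHANNELS + N_ATCHLEY_FACTORS,
        }[self.scheme]


@dataclass
class EncodedTensor:
    """Fixed-length (pad_length x channels) representation of one sequence."""

    values: np.ndarray
    source_id: str
    true_length: int

    def __post_init__(self) -> None:
        if self.values.ndim != 2:
            raise ValueError("encoded values must be a 2-D matrix")
        if self.true_length > self.values.shape[0]:
            raise ValueError("true_length exceeds padded length")


def _check_length(record: SequenceRecord, config: EncodingConfig) -> None:
    if len(record) > config.pad_length:
        raise ValueError(
            f"record {record.id!r}: length {len(record)} exceeds "
            f"pad_length {config.pad_length}"
        )


def encode_one_hot(record: SequenceRecord, config: EncodingConfig) -> EncodedTensor:
    """Indicator encoding: one channel set per position, pad channel in the tail."""
    _check_length(record, config)
    alphabet = config.alphabet
    mat = np.zeros((config.pad_length, N_ONE_HOT_CHANNELS), dtype=np.float32)
    for pos, residue in enumerate(record.sequence):
        mat[pos, alphabet.index_of(residue)] = 1.0
    pad_channel = alphabet.index_of(alphabet.pad_symbol)
    mat[len(record):, pad_channel] = 1.0
    return EncodedTensor(mat, record.id, len(record))


def encode_atchley(
    record: SequenceRecord,
    config: EncodingConfig,
    table: Optional[AtchleyTable] = None,
) -> EncodedTensor:
    """Five-factor physicochemical encoding; padding rows are all-zero."""
    _check_length(record, config)
    table = table or default_atchley_table()
    mat = np.zeros((config.pad_length, N_ATCHLEY_FACTORS), dtype=np.float32)
    for pos, residue in enumerate(record.sequence):
        mat[pos] = table[residue]
    return EncodedTensor(mat, record.id, len(record))


def encode_combined(
    record: SequenceRecord,
    config: EncodingConfig,
    table: Optional[AtchleyTable] = None,
) -> EncodedTensor:
    """Concatenation of one-hot (channels 0-27) and Atchley (channels 28-32)."""
    _check_length(record, config)
    one_hot = encode_one_hot(record, config)
    atchley = encode_atchley(record, config, table)
    mat = np.concatenate([one_hot.values, atchley.values], axis=1)
    return EncodedTensor(mat, record.id, len(record))


_ENCODERS = {
    "one_hot": lambda r, c, t: encode_one_hot(r, c),
    "atchley": encode_atchley,
    "combined": encode_combined,
}


def encode_record(
    record: SequenceRecord,
    config: EncodingConfig,
    table: Optional[AtchleyTable] = None,
) -> EncodedTensor:
    """Encode one record under the configured scheme."""
    return _ENCODERS[config.scheme](record, config, table)


def encode_batch(
    records: Sequence[SequenceRecord],
    config: EncodingConfig,
    table: Optional[AtchleyTable] = None,
) -> tuple[list[EncodedTensor], np.ndarray]:
    """Encode records in order; labels are 1 for positives, 0 otherwise."""
    tensors = []
    for record in records:
        try:
            tensors.append(encode_record(record, config, table))
        except ValueError as exc:
            raise ValueError(f"while encoding {record.id!r}: {exc}") from exc
    labels = np.array([1 if r.label == Label.POSITIVE else 0 for r in records])
    return tensors, labels


def stack_tensors(tensors: Sequence[EncodedTensor]) -> np.ndarray:
    """Stack encoded tensors into an (n, pad_length, channels) array."""
    return np.stack([t.values for t in tensors]) if tensors else np.empty((0, 0, 0))
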