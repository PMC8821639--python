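"""Fixed residue alphabet shared by all encoders.

The one-hot feature space is 28-dimensional: the 20 canonical amino acids,
the six extended IUPAC/UniProt ambiguity or rare-residue codes (B, J, O, U,
X, Z), the translation-stop artifact ``*``, and one designated padding
symbol. The padding symbol owns its own indicator channel, which is what
makes the space 28- rather than 27-dimensional.
"""

from __future__ import annotations

from dataclasses import dataclass, field

CANONICAL_RESIDUES = "ACDEFGHIKLMNPQRSTVWY"
EXTENDED_RESIDUES = "BJOUXZ"
STOP_SYMBOL = "*"
DEFAULT_PAD_SYMBOL = "-"


@dataclass(frozen=True)
class ResidueAlphabet:
    """Ordered 28-symbol alphabet mapping residue characters to channels.

    Channel order is fixed: canonical residues (alphabetical), extended
    codes, ``*``, then the pad symbol in the last channel.
    """

    symbols: tuple[str, ...] = field(
        default=tuple(CANONICAL_RESIDUES + EXTENDED_RESIDUES + STOP_SYMBOL + DEFAULT_PAD_SYMBOL)
    )
    pad_symbol: str = DEFAULT_PAD_SYMBOL

    def __post_init__(self) -> None:
        if len(self.symbols) != 28:
            raise ValueError(f"alphabet must have exactly 28 symbols, got {len(self.symbols)}")
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be distinct")
        missing = set(CANONICAL_RESIDUES) - set(self.symbols)
        if missing:
            raise ValueError(f"canonical residues missing from alphabet: {sorted(missing)}")
        if self.pad_symbol not in self.symbols:
            raise ValueError("pad symbol must be a member of the alphabet")

    def __len__(self) -> int:
        return len(self.symbols)

    def index_of(self, symbol: str) -> int:
        """Channel index of *symbol* in [0, 27]."""
        try:
            return self.symbols.index(symbol)
        except ValueError:
            raise KeyError(f"symbol {symbol!r} not in alphabet") from None

    @property
    def residue_symbols(self) -> tuple[str, ...]:
        """The 27 non-pad symbols sequences may contain."""
        return tuple(s for s in self.symbols if s != self.pad_symbol)

    def __contains__(self, symbol: str) -> bool:
        return symbol in self.symbols


DEFAULT_ALPHABET = ResidueAlphabet()
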