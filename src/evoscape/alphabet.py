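"""Symbol alphabets for aligned sequences.

The canonical alphabet used throughout the package is the 21-state amino
acid alphabet with the alignment gap as the first state, in the fixed order
``-ACDEFGHIKLMNPQRSTVWY``.  All parameter files, frequency tables and score
matrices index amino acids in this order.  Smaller generic alphabets (e.g.
q=4 toy alphabets) are supported for fast tests and enumeration oracles.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["Alphabet", "PROTEIN", "AMINO_ACIDS", "GAP"]

GAP = "-"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"


@dataclass(frozen=True)
class Alphabet:
    """An ordered set of sequence symbols with optional gap symbol.

    Parameters
    ----------
    symbols : str
        The ordered symbols; index lookup is a bijection onto ``range(q)``.
    gap : str or None
        The gap symbol, which must occur exactly once in `symbols` if given.
        Gapped positions are frozen during evolutionary simulations.
    """

    symbols: str
    gap: str | None = GAP
    _index: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(set(self.symbols)) != len(self.symbols):
            raise ValueError("alphabet symbols must be unique")
        if self.gap is not None and self.symbols.count(self.gap) != 1:
            raise ValueError(f"gap symbol {self.gap!r} must occur exactly once")
        object.__setattr__(self, "_index", {s: i for i, s in enumerate(self.symbols)})

    @property
    def q(self) -> int:
        return len(self.symbols)

    @property
    def gap_index(self) -> int | None:
        return None if self.gap is None else self._index[self.gap]

    def index(self, symbol: str) -> int:
        try:
            return self._index[symbol]
        except KeyError:
            raise ValueError(f"symbol {symbol!r} not in alphabet {self.symbols!r}") from None

    def encode(self, seq) -> np.ndarray:
        """Map a string (or iterable of symbols) to an int8 index array."""
        return np.fromiter((self.index(s) for s in seq), dtype=np.int8, count=len(seq))

    def decode(self, indices) -> str:
        arr = np.asarray(indices)
        if arr.size and (arr.min() < 0 or arr.max() >= self.q):
            raise ValueError("index out of alphabet range")
        return "".join(self.symbols[int(i)] for i in arr)

    def encode_msa(self, seqs) -> np.ndarray:
        """Encode a list of equal-length sequences into an (M, L) array."""
        seqs = list(seqs)
        if not seqs:
            raise ValueError("empty alignment")
        lengths = {len(s) for s in seqs}
        if len(lengths) != 1:
            raise ValueError("sequences have unequal lengths")
        return np.vstack([self.encode(s) for s in seqs])


#: The canonical gap + 20 amino acid alphabet (gap first).
PROTEIN = Alphabet(GAP + AMINO_ACIDS, gap=GAP)
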