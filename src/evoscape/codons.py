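"""The standard genetic code and single-nucleotide codon accessibility.

Mutations happen at the nucleotide level, so the amino acids reachable from
a given site in one mutational step are constrained by the current codon:
``A_acc(codon)`` is the set of amino acids encoded by the codon itself or by
any of its nine single-nucleotide neighbors, excluding stop codons (stops
are never allowed in an evolving coding sequence).  The codon's own amino
acid is always accessible, via the identity or a synonymous change.

Codons are indexed 0..63 in lexicographic ACGT order; the gap triplet
``---`` (paired with the alignment gap in the amino acid sequence) is
represented by the sentinel index -1 and is never mutated.

All lookup tables are precomputed as NumPy arrays so the evolutionary kernel
can run under numba.  Amino acid indices follow :data:`evoscape.alphabet.PROTEIN`
(gap = 0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from Bio.Data import CodonTable

from .alphabet import PROTEIN

__all__ = [
    "NUCLEOTIDES",
    "CODONS",
    "GAP_CODON",
    "codon_index",
    "translate",
    "accessible_amino_acids",
    "codons_within_one",
    "EvolvingState",
    "assign_codons",
    "validate_dna",
]

NUCLEOTIDES = "ACGT"
GAP_CODON = "---"

#: all 64 codons in lexicographic ACGT order
CODONS = [a + b + c for a in NUCLEOTIDES for b in NUCLEOTIDES for c in NUCLEOTIDES]
_CODON_INDEX = {c: k for k, c in enumerate(CODONS)}

_STOP = -2  # sentinel amino acid index for stop codons
_GAP_IDX = -1  # sentinel codon index for the gap triplet

_table = CodonTable.unambiguous_dna_by_id[1]  # the standard code

#: amino acid index (PROTEIN alphabet) per codon; -2 marks stop codons
CODON_AA = np.full(64, _STOP, dtype=np.int8)
for _codon, _aa in _table.forward_table.items():
    if set(_codon) <= set(NUCLEOTIDES):
        CODON_AA[_CODON_INDEX[_codon]] = PROTEIN.index(_aa)

SENSE_CODONS = [c for c in CODONS if CODON_AA[_CODON_INDEX[c]] != _STOP]

#: synonymous sense codons per amino acid index, -1 padded
SYNONYMOUS = np.full((21, 6), -1, dtype=np.int8)
SYNONYMOUS_COUNT = np.zeros(21, dtype=np.int8)
for _k, _a in enumerate(CODON_AA):
    if _a >= 0:
        SYNONYMOUS[_a, SYNONYMOUS_COUNT[_a]] = _k
        SYNONYMOUS_COUNT[_a] += 1


def _neighbors(k: int) -> list[int]:
    """Codon indices at nucleotide Hamming distance exactly 1."""
    out = []
    for pos, mult in ((0, 16), (1, 4), (2, 1)):
        digit = (k // mult) % 4
        for d in range(4):
            if d != digit:
                out.append(k + (d - digit) * mult)
    return out


# accessibility tables: amino acids reachable by <= 1 nucleotide change
ACC_AA = np.full((64, 8), -1, dtype=np.int8)
ACC_COUNT = np.zeros(64, dtype=np.int8)
# sense codons of amino acid a within <= 1 change of codon k, -1 padded
# (up to 5 for six-codon amino acids: the codon itself + 3 synonymous
# third-position neighbors + a first-position one)
CODONS_NEAR = np.full((64, 21, 6), -1, dtype=np.int8)
CODONS_NEAR_COUNT = np.zeros((64, 21), dtype=np.int8)

for _k in range(64):
    if CODON_AA[_k] == _STOP:
        continue
    reachable = [_k] + _neighbors(_k)
    seen: list[int] = []
    for _n in reachable:
        _a = int(CODON_AA[_n])
        if _a == _STOP:
            continue
        if _a not in seen:
            seen.append(_a)
        CODONS_NEAR[_k, _a, CODONS_NEAR_COUNT[_k, _a]] = _n
        CODONS_NEAR_COUNT[_k, _a] += 1
    seen.sort()
    ACC_AA[_k, : len(seen)] = seen
    ACC_COUNT[_k] = len(seen)


def codon_index(codon: str) -> int:
    """Index of a codon string (gap triplet -> -1)."""
    if codon == GAP_CODON:
        return _GAP_IDX
    try:
        return _CODON_INDEX[codon.upper()]
    except KeyError:
        raise ValueError(f"malformed codon {codon!r}") from None


def _require_sense(codon: str) -> int:
    k = codon_index(codon)
    if k == _GAP_IDX:
        raise ValueError("gap codons are never mutated")
    if CODON_AA[k] == _STOP:
        raise ValueError(f"stop codon {codon!r} not allowed")
    return k


def translate(dna: str) -> str:
    """Translate a codon-aligned DNA string (standard code; '---' -> '-')."""
    if len(dna) % 3 != 0:
        raise ValueError("DNA length is not a multiple of 3")
    out = []
    for i in range(0, len(dna), 3):
        codon = dna[i : i + 3].upper()
        if codon == GAP_CODON:
            out.append(PROTEIN.gap)
            continue
        k = codon_index(codon)
        a = int(CODON_AA[k])
        if a == _STOP:
            raise ValueError(f"stop codon {codon} at codon position {i // 3}")
        out.append(PROTEIN.symbols[a])
    return "".join(out)


def accessible_amino_acids(codon: str) -> set[str]:
    """A_acc: amino acids reachable by at most one nucleotide mutation.

    Stop codons are excluded from the neighborhood; the codon's own amino
    acid is always a member (reachable via the identity/synonymous change).
    """
    k = _require_sense(codon)
    return {PROTEIN.symbols[a] for a in ACC_AA[k, : ACC_COUNT[k]]}


def codons_within_one(codon: str, b: str) -> set[str]:
    """Sense codons of amino acid `b` within one nucleotide of `codon`."""
    k = _require_sense(codon)
    a = PROTEIN.index(b)
    n = CODONS_NEAR_COUNT[k, a]
    if n == 0:
        raise ValueError(f"{b!r} is not accessible from codon {codon!r}")
    return {CODONS[c] for c in CODONS_NEAR[k, a, :n]}


@dataclass
class EvolvingState:
    """Paired codon and amino acid representations of an evolving sequence.

    ``codons`` is an int8 array of codon indices (-1 for the gap triplet),
    ``aa`` the translated amino acid index array over the PROTEIN alphabet.
    The two are kept mutually consistent at all times.  ``codons=None``
    marks an amino-acid-only state (toy alphabets / SEEC mode) with no
    nucleotide layer.
    """

    codons: np.ndarray | None
    aa: np.ndarray

    def __post_init__(self) -> None:
        self.aa = np.ascontiguousarray(self.aa, dtype=np.int8)
        if self.codons is not None:
            self.codons = np.ascontiguousarray(self.codons, dtype=np.int8)
            if self.codons.shape != self.aa.shape or self.codons.ndim != 1:
                raise ValueError("codon and amino acid arrays must be 1-D and equal length")
        self.validate()

    @property
    def L(self) -> int:
        return self.aa.shape[0]

    def validate(self) -> None:
        if self.codons is None:
            return
        for i, k in enumerate(self.codons):
            if k == _GAP_IDX:
                if self.aa[i] != PROTEIN.gap_index:
                    raise ValueError(f"gap codon at site {i} with non-gap amino acid")
            else:
                a = int(CODON_AA[k])
                if a == _STOP:
                    raise ValueError(f"stop codon at site {i}")
                if a != self.aa[i]:
                    raise ValueError(
                        f"codon {CODONS[k]} at site {i} encodes "
                        f"{PROTEIN.symbols[a]} but amino acid is {PROTEIN.symbols[self.aa[i]]}"
                    )

    @property
    def dna(self) -> str:
        if self.codons is None:
            raise ValueError("state has no nucleotide layer")
        return "".join(GAP_CODON if k == _GAP_IDX else CODONS[k] for k in self.codons)

    @property
    def protein(self) -> str:
        return PROTEIN.decode(self.aa)

    def copy(self) -> "EvolvingState":
        codons = None if self.codons is None else self.codons.copy()
        return EvolvingState(codons, self.aa.copy())


def assign_codons(aa, mode: str = "random_synonymous", seed: int | None = 0,
                  dna: str | None = None) -> EvolvingState:
    """Build a consistent :class:`EvolvingState` for an amino acid sequence.

    Parameters
    ----------
    aa : str or int array
        Aligned amino acid sequence over the PROTEIN alphabet.
    mode : {"random_synonymous", "first_codon", "given_dna"}
        ``random_synonymous`` draws each codon uniformly among the synonymous
        sense codons (seeded); ``first_codon`` takes the lexicographically
        first; ``given_dna`` validates a user-supplied coding sequence.
    """
    aa_idx = PROTEIN.encode(aa) if isinstance(aa, str) else np.asarray(aa, dtype=np.int8)
    if mode == "given_dna":
        if dna is None:
            raise ValueError("mode='given_dna' requires a dna argument")
        if len(dna) != 3 * len(aa_idx):
            raise ValueError("DNA length does not match 3x the protein length")
        codons = np.empty(len(aa_idx), dtype=np.int8)
        for i in range(len(aa_idx)):
            codon = dna[3 * i : 3 * i + 3].upper()
            k = codon_index(codon)
            codons[i] = k
            want = PROTEIN.symbols[aa_idx[i]]
            if k == _GAP_IDX:
                got = PROTEIN.gap
            else:
                a = int(CODON_AA[k])
                if a == _STOP:
                    raise ValueError(f"stop codon {codon} at site {i}")
                got = PROTEIN.symbols[a]
            if got != want:
                raise ValueError(f"codon {codon} at site {i} encodes {got!r}, expected {want!r}")
        return EvolvingState(codons, aa_idx)

    rng = np.random.default_rng(seed)
    codons = np.empty(len(aa_idx), dtype=np.int8)
    for i, a in enumerate(aa_idx):
        if a == PROTEIN.gap_index:
            codons[i] = _GAP_IDX
            continue
        n = int(SYNONYMOUS_COUNT[a])
        if n == 0:
            raise ValueError(f"no codon for symbol index {a} at site {i}")
        if mode == "random_synonymous":
            codons[i] = SYNONYMOUS[a, rng.integers(n)]
        elif mode == "first_codon":
            codons[i] = SYNONYMOUS[a, :n].min()
        else:
            raise ValueError(f"unknown mode {mode!r}")
    return EvolvingState(codons, aa_idx)


def validate_dna(dna: str, aa) -> "object":
    """Codon-level consistency report of a coding sequence against a protein.

    Returns a pandas DataFrame with one row per codon position: the codon,
    the amino acid it encodes, the expected amino acid, and a status
    (``ok`` / ``mismatch`` / ``stop`` / ``malformed``).  Suitable for TSV
    export; unlike :func:`assign_codons` it does not raise on the first
    problem.
    """
    import pandas as pd

    aa_idx = PROTEIN.encode(aa) if isinstance(aa, str) else np.asarray(aa, dtype=np.int8)
    rows = []
    n = min(len(dna) // 3, len(aa_idx))
    for i in range(n):
        codon = dna[3 * i : 3 * i + 3].upper()
        want = PROTEIN.symbols[aa_idx[i]]
        try:
            k = codon_index(codon)
        except ValueError:
            rows.append((i, codon, "", want, "malformed"))
            continue
        if k == _GAP_IDX:
            got = PROTEIN.gap
            status = "ok" if got == want else "mismatch"
        elif CODON_AA[k] == _STOP:
            got = "*"
            status = "stop"
        else:
            got = PROTEIN.symbols[CODON_AA[k]]
            status = "ok" if got == want else "mismatch"
        rows.append((i, codon, got, want, status))
    if len(dna) // 3 != len(aa_idx):
        rows.append((n, "", "", "", "length_mismatch"))
    return pd.DataFrame(rows, columns=["site", "codon", "encodes",
                                       "expected", "status"])
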