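"""Library-level statistics for comparing sequence ensembles.

The statistics used to compare simulated and experimentally evolved
libraries: Hamming distances to the wildtype, site-specific amino acid
frequency spectra f_i(a), rank correlations between spectra, and the
energy-versus-distance profile whose slope calibrates the selection
temperature.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .alphabet import PROTEIN, Alphabet
from .codons import ACC_AA, ACC_COUNT, EvolvingState
from .landscape import energy

__all__ = ["SiteFrequencyTable", "hamming_distance", "hamming_to_reference",
           "site_frequencies", "spectra_correlation", "energy_distance_profile"]


@dataclass
class SiteFrequencyTable:
    """f_i(a): fraction of library sequences with symbol a at site i."""

    values: np.ndarray  # (L, q)
    n_sequences: int
    weighted: bool = False
    alphabet: Alphabet = PROTEIN

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        rows = self.values.sum(axis=1)
        if not np.allclose(rows, 1.0, atol=1e-9):
            raise ValueError("frequency rows must sum to 1")
        if (self.values < 0).any() or (self.values > 1).any():
            raise ValueError("frequencies must lie in [0, 1]")

    @property
    def L(self) -> int:
        return self.values.shape[0]

    @property
    def q(self) -> int:
        return self.values.shape[1]

    def to_frame(self) -> pd.DataFrame:
        L, q = self.values.shape
        sym = list(self.alphabet.symbols) if self.alphabet.q == q else list(range(q))
        recs = [(i, sym[a], self.values[i, a]) for i in range(L) for a in range(q)]
        return pd.DataFrame(recs, columns=["site", "aa", "frequency"])


def _as_indices(seq, alphabet: Alphabet) -> np.ndarray:
    if isinstance(seq, str):
        return alphabet.encode(seq)
    if isinstance(seq, EvolvingState):
        return seq.aa
    return np.asarray(seq)


def hamming_distance(seq_a, seq_b, alphabet: Alphabet = PROTEIN) -> int:
    """Number of positions with differing symbols."""
    a = _as_indices(seq_a, alphabet)
    b = _as_indices(seq_b, alphabet)
    if a.shape != b.shape:
        raise ValueError("sequences have different lengths")
    return int((a != b).sum())


def hamming_to_reference(msa: np.ndarray, reference) -> np.ndarray:
    """Per-sequence Hamming distance of an (M, L) alignment to a reference."""
    ref = _as_indices(reference, PROTEIN)
    return (np.asarray(msa) != ref[None, :]).sum(axis=1)


def site_frequencies(msa, weights=None, alphabet: Alphabet = PROTEIN,
                     q: int | None = None) -> SiteFrequencyTable:
    """Empirical (optionally weighted) site frequency table of an alignment."""
    if isinstance(msa, np.ndarray):
        X = msa.astype(np.intp)
        q = q or max(int(X.max()) + 1, alphabet.q if alphabet else 0)
    else:
        X = alphabet.encode_msa(msa).astype(np.intp)
        q = q or alphabet.q
    if X.size == 0:
        raise ValueError("empty alignment")
    M, L = X.shape
    if weights is None:
        w = np.ones(M)
        weighted = False
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (M,):
            raise ValueError("weights length must match alignment depth")
        weighted = True
    f = np.empty((L, q))
    for i in range(L):
        f[i] = np.bincount(X[:, i], weights=w, minlength=q)
    f /= w.sum()
    return SiteFrequencyTable(f, n_sequences=M, weighted=weighted, alphabet=alphabet)


def _accessible_mask(wildtype: EvolvingState, q: int) -> np.ndarray:
    """(L, q) mask of amino acids reachable from the wildtype codons."""
    if wildtype.codons is None:
        raise ValueError("accessible_only filtering requires a wildtype with codons")
    mask = np.zeros((wildtype.L, q), dtype=bool)
    for i, k in enumerate(wildtype.codons):
        if k < 0:
            continue
        for a in ACC_AA[k, : ACC_COUNT[k]]:
            mask[i, a] = True
    return mask


def spectra_correlation(f1: SiteFrequencyTable, f2: SiteFrequencyTable,
                        entry_filter: str = "all",
                        wildtype: EvolvingState | None = None) -> float:
    """Spearman rank correlation between two frequency spectra.

    The correlation runs over selected (site, symbol) entries:
    ``all`` uses every entry, ``non_wildtype`` drops the wildtype symbol at
    each site, and ``accessible_only`` keeps only amino acids reachable from
    the wildtype codon by one nucleotide change (requires `wildtype`).
    """
    if f1.values.shape != f2.values.shape:
        raise ValueError("frequency tables have different shapes")
    L, q = f1.values.shape
    mask = np.ones((L, q), dtype=bool)
    if entry_filter == "non_wildtype":
        if wildtype is None:
            raise ValueError("entry_filter='non_wildtype' requires a wildtype")
        mask[np.arange(L), wildtype.aa.astype(np.intp)] = False
    elif entry_filter == "accessible_only":
        mask = _accessible_mask(wildtype, q)
    elif entry_filter != "all":
        raise ValueError(f"unknown entry_filter {entry_filter!r}")
    x = f1.values[mask]
    y = f2.values[mask]
    if x.size < 3:
        raise ValueError("fewer than 3 entries after filtering")
    rho = stats.spearmanr(x, y).statistic
    return float(rho)


def energy_distance_profile(msa: np.ndarray, model, wildtype,
                            bins=None) -> pd.DataFrame:
    """Per-distance summary of sequence energies relative to the wildtype.

    Returns a table with one row per Hamming distance (or per bin if `bins`
    is given): count, mean dE = E(seq) - E(wildtype), and sd.
    """
    X = np.asarray(msa)
    if X.size == 0:
        raise ValueError("empty alignment")
    wt = _as_indices(wildtype, model.alphabet)
    e_wt = energy(model, wt.astype(np.intp))
    d = hamming_to_reference(X, wt)
    dE = np.array([energy(model, row.astype(np.intp)) for row in X]) - e_wt
    df = pd.DataFrame({"distance": d, "dE": dE})
    if bins is not None:
        df["distance"] = pd.cut(df["distance"], bins=bins).apply(lambda iv: iv.mid)
    out = (df.groupby("distance", observed=True)["dE"]
             .agg(n="size", mean_dE="mean", sd_dE="std")
             .reset_index())
    out["sd_dE"] = out["sd_dE"].fillna(0.0)
    return out
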