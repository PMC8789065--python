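"""Coevolution-based contact scoring and evaluation.

Pair scores are computed by a Gaussian direct-coupling analysis: the
alignment is one-hot encoded over q-1 states per site (the last alphabet
state is dropped; the gap is an ordinary state), weighted one- and two-site
frequencies are regularized by a pseudocount toward the uniform independent
model, and the inverse of the resulting covariance matrix provides coupling
blocks whose Frobenius norms, after average-product correction (APC), rank
candidate contacts.  Prediction quality is the positive predictive value
(PPV): the fraction of true contacts among the top-n ranked pairs (n = 100
in the protein-family setting; planted-contact landscapes use n of the
order of the number of planted contacts).

The parameter scan maps PPV over (selection temperature, divergence,
library depth) grids with replicate simulations, reproducing the emergence
of epistatic signal with library size and divergence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .contactmap import ContactMap, contact_map_from_distances  # noqa: F401 (re-export)
from .evolver import EvolverConfig, evolve_library, subsample_msa

__all__ = ["ContactMap", "contact_map_from_distances", "ScoreMatrix",
           "sequence_weights", "gauss_dca_scores", "apc_correction", "ppv",
           "ppv_null", "ranked_pairs", "parameter_scan"]


@dataclass
class ScoreMatrix:
    """Symmetric L x L pair-score matrix; diagonal entries are ignored."""

    values: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("score matrix must be square")
        if not np.allclose(v, v.T, atol=1e-8):
            raise ValueError("score matrix must be symmetric")
        self.values = 0.5 * (v + v.T)

    @property
    def L(self) -> int:
        return self.values.shape[0]


def sequence_weights(msa: np.ndarray, identity_threshold: float | str = 0.8) -> np.ndarray:
    """Phylogenetic reweighting: w_s = 1 / #{t : identity(s,t) >= threshold}.

    ``identity_threshold="off"`` returns unit weights (the appropriate
    choice for simulated libraries of independent chains); threshold 1.0
    down-weights exact duplicates only.
    """
    X = np.asarray(msa)
    if X.size == 0:
        raise ValueError("empty alignment")
    if isinstance(identity_threshold, str):
        if identity_threshold != "off":
            raise ValueError(f"unknown reweighting mode {identity_threshold!r}")
        return np.ones(X.shape[0])
    if not 0 < identity_threshold <= 1:
        raise ValueError("identity threshold must lie in (0, 1]")
    M, L = X.shape
    counts = np.zeros(M)
    chunk = max(1, 2_000_000 // max(M * 1, 1))
    for s0 in range(0, M, chunk):
        block = X[s0 : s0 + chunk]                      # (c, L)
        ident = (block[:, None, :] == X[None, :, :]).mean(axis=2)
        counts[s0 : s0 + chunk] = (ident >= identity_threshold).sum(axis=1)
    return 1.0 / counts


def _frequencies(X: np.ndarray, q: int, weights: np.ndarray, pseudocount: float):
    """Pseudocounted weighted 1- and 2-site frequencies on q-1 states."""
    M, L = X.shape
    d = q - 1
    w = weights / weights.sum()
    one_hot = np.zeros((M, L * d))
    keep = X < d
    rows, cols = np.nonzero(keep)
    one_hot[rows, cols * d + X[rows, cols]] = 1.0
    fi = (w[:, None] * one_hot).sum(axis=0)                    # (L*d,)
    fij = (one_hot * w[:, None]).T @ one_hot                   # (L*d, L*d)
    lam = pseudocount
    fi = (1 - lam) * fi + lam / q
    fij = (1 - lam) * fij + lam / q**2
    # diagonal blocks: P_ii(a,b) = delta_ab f_i(a) after pseudocounting
    for i in range(L):
        sl = slice(i * d, (i + 1) * d)
        block = np.diag(fi[sl])
        fij[sl, sl] = block
    return fi, fij


def gauss_dca_scores(msa: np.ndarray, pseudocount: float = 0.6,
                     weights: np.ndarray | None = None,
                     q: int | None = None, apc: bool = True) -> ScoreMatrix:
    """Gaussian-DCA pair scores of an alignment.

    The covariance matrix C = f_ij - f_i f_j over the (q-1)-state one-hot
    encoding is inverted; the score of pair (i, j) is the Frobenius norm of
    the (i, j) coupling block, APC-corrected by default.  Raise the
    pseudocount if the covariance is reported singular.
    """
    X = np.asarray(msa, dtype=np.intp)
    if X.ndim != 2 or X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need an alignment with M >= 2 sequences and L >= 2 sites")
    if not 0 < pseudocount < 1:
        raise ValueError("pseudocount must lie in (0, 1)")
    M, L = X.shape
    q = q or int(X.max()) + 1
    w = np.ones(M) if weights is None else np.asarray(weights, dtype=float)
    fi, fij = _frequencies(X, q, w, pseudocount)
    C = fij - np.outer(fi, fi)
    try:
        K = np.linalg.inv(C)
    except np.linalg.LinAlgError as err:
        raise np.linalg.LinAlgError(
            "singular covariance matrix; raise the pseudocount or provide "
            "more / more diverse sequences") from err
    d = q - 1
    blocks = K.reshape(L, d, L, d)
    S = np.sqrt(np.einsum("iajb,iajb->ij", blocks, blocks))
    np.fill_diagonal(S, 0.0)
    S = 0.5 * (S + S.T)
    scores = ScoreMatrix(S)
    return apc_correction(scores) if apc else scores


def apc_correction(scores: ScoreMatrix) -> ScoreMatrix:
    """Average-product correction: S'_ij = S_ij - S_i. S_.j / S_.. .

    Row/column/total means run over off-diagonal entries.  An all-zero
    matrix is returned unchanged.
    """
    S = scores.values.copy()
    L = S.shape[0]
    if L < 2 or not S.any():
        return ScoreMatrix(S)
    off = ~np.eye(L, dtype=bool)
    row_mean = (S * off).sum(axis=1) / (L - 1)
    tot_mean = (S * off).sum() / (L * (L - 1))
    corr = S - np.outer(row_mean, row_mean) / tot_mean
    corr[~off] = 0.0
    return ScoreMatrix(0.5 * (corr + corr.T))


def ranked_pairs(scores: ScoreMatrix, min_separation: int) -> list[tuple[int, int]]:
    """Eligible pairs sorted by descending score; ties broken by (i, j)."""
    L = scores.L
    pairs = [(i, j) for i in range(L) for j in range(i + min_separation, L)]
    pairs.sort(key=lambda p: (-scores.values[p[0], p[1]], p[0], p[1]))
    return pairs


def ppv(scores: ScoreMatrix, contact_map: ContactMap, n_predictions: int = 100) -> float:
    """Fraction of true contacts among the top-n ranked predictions."""
    pairs = ranked_pairs(scores, contact_map.min_separation)
    if n_predictions > len(pairs):
        raise ValueError(f"only {len(pairs)} eligible pairs for n={n_predictions}")
    top = pairs[:n_predictions]
    hits = sum(1 for p in top if p in contact_map)
    return hits / n_predictions


def ppv_null(contact_map: ContactMap, n_predictions: int,
             n_permutations: int = 1000, seed: int = 0):
    """Monte-Carlo null: PPV of random rankings (mean, sd over permutations).

    The expectation equals the contact density among eligible pairs.
    """
    L = contact_map.L
    s = contact_map.min_separation
    pairs = [(i, j) for i in range(L) for j in range(i + s, L)]
    if n_predictions > len(pairs):
        raise ValueError("n_predictions exceeds the number of eligible pairs")
    is_contact = np.array([p in contact_map for p in pairs])
    rng = np.random.default_rng(seed)
    vals = np.empty(n_permutations)
    for k in range(n_permutations):
        idx = rng.permutation(len(pairs))[:n_predictions]
        vals[k] = is_contact[idx].mean()
    return float(vals.mean()), float(vals.std(ddof=1))


def parameter_scan(model, wildtype, T_values, snapshot_steps, library_sizes,
                   n_replicates: int, contact_map: ContactMap, seed: int = 0,
                   n_predictions: int = 100, pseudocount: float = 0.6,
                   reweight: str | float = "off", mode: str = "codon") -> pd.DataFrame:
    """PPV grid over (T, divergence, library depth) with replicate runs.

    For each (T, replicate) a single library of max(library_sizes) chains is
    simulated with snapshots at all requested steps; smaller libraries are
    obtained by seeded subsampling without replacement.  Returns one row per
    (T, steps, M) with mean/sd PPV and mean Hamming distance over
    replicates, plus the per-replicate values in long form under
    ``result.attrs['replicates']``.
    """
    steps = tuple(sorted(set(int(s) for s in snapshot_steps)))
    sizes = sorted(set(int(m) for m in library_sizes))
    M_max = sizes[-1]
    rows = []
    for T in T_values:
        for rep in range(n_replicates):
            lib_seed = int(np.random.SeedSequence([seed, rep, hash(float(T)) % (2**31)])
                           .generate_state(1)[0] % (2**31))
            lib = evolve_library(wildtype, model, EvolverConfig(
                T=T, n_steps=steps[-1], n_chains=M_max,
                snapshot_steps=steps, seed=lib_seed, mode=mode))
            for s in steps:
                X = lib.aa[s]
                dists = lib.distances[s]
                for M in sizes:
                    sub_seed = int(np.random.SeedSequence([seed, rep, s, M])
                                   .generate_state(1)[0] % (2**31))
                    rng = np.random.default_rng(sub_seed)
                    idx = rng.choice(M_max, size=M, replace=False)
                    sub = X[idx]
                    w = sequence_weights(sub, reweight) if reweight != "off" else None
                    scores = gauss_dca_scores(sub, pseudocount=pseudocount,
                                              weights=w, q=model.q)
                    rows.append({
                        "T": float(T), "steps": s, "M": M, "replicate": rep,
                        "ppv": ppv(scores, contact_map, n_predictions),
                        "mean_hamming": float(dists[idx].mean()),
                    })
    reps = pd.DataFrame(rows)
    out = (reps.groupby(["T", "steps", "M"])
               .agg(mean_ppv=("ppv", "mean"), sd_ppv=("ppv", "std"),
                    mean_hamming=("mean_hamming", "mean"),
                    n_replicates=("ppv", "size"))
               .reset_index())
    out["sd_ppv"] = out["sd_ppv"].fillna(0.0)
    out.attrs["replicates"] = reps
    return out
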