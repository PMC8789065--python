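"""Potts and profile sequence landscapes.

A Potts (pairwise graphical) model over aligned sequences assigns the
statistical energy

    E(a_1..a_L) = - sum_i h_i(a_i) - sum_{i<j} J_ij(a_i, a_j),

where ``h`` are position- and symbol-specific fields and ``J`` pairwise
epistatic couplings.  Low energy corresponds to high model probability
P = exp(-E)/Z and is used throughout as a proxy for high fitness.  A profile
model keeps only the fields (site-independence, no epistasis) and serves as
the non-epistatic baseline.

Energies are defined up to a gauge transformation; :func:`zero_sum_gauge`
maps a model to the canonical zero-sum gauge without changing any energy
difference between sequences.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np

from .alphabet import PROTEIN, Alphabet

__all__ = [
    "PottsModel",
    "ProfileModel",
    "energy",
    "delta_energy",
    "mutant_scan",
    "conditional_distribution",
    "zero_sum_gauge",
    "profile_from_msa",
    "read_params",
    "write_params",
]

logger = logging.getLogger(__name__)


@dataclass
class PottsModel:
    """Fields ``h[i, a]`` and couplings ``J[i, j, a, b]`` of a Potts landscape.

    Couplings satisfy the symmetry ``J[i, j, a, b] == J[j, i, b, a]`` and
    ``J[i, i] == 0``; both are enforced at construction.
    """

    h: np.ndarray
    J: np.ndarray
    alphabet: Alphabet = PROTEIN

    def __post_init__(self) -> None:
        self.h = np.ascontiguousarray(self.h, dtype=np.float64)
        self.J = np.ascontiguousarray(self.J, dtype=np.float64)
        L, q = self.h.shape
        if self.J.shape != (L, L, q, q):
            raise ValueError(f"couplings shape {self.J.shape} incompatible with fields {self.h.shape}")
        if not (np.isfinite(self.h).all() and np.isfinite(self.J).all()):
            raise ValueError("non-finite model parameters")
        if not np.allclose(self.J, np.transpose(self.J, (1, 0, 3, 2)), atol=1e-8):
            raise ValueError("couplings violate J[i,j,a,b] == J[j,i,b,a]")
        # exact symmetrization + zero diagonal
        self.J = 0.5 * (self.J + np.transpose(self.J, (1, 0, 3, 2)))
        self.J[np.arange(L), np.arange(L)] = 0.0

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    @property
    def has_couplings(self) -> bool:
        return True

    def coupling_field(self, seq: np.ndarray, site: int) -> np.ndarray:
        """Local field h_i(.) + sum_{j != i} J_ij(., a_j) seen by `site`."""
        idx = np.arange(self.L)
        # J[site, j, :, seq[j]] for all j; J[site, site] is zero
        context = self.J[site, idx, :, seq[idx]]  # (L, q)
        return self.h[site] + context.sum(axis=0)


@dataclass
class ProfileModel:
    """Independent-site landscape with fields only (no epistasis)."""

    h: np.ndarray
    alphabet: Alphabet = PROTEIN

    def __post_init__(self) -> None:
        self.h = np.ascontiguousarray(self.h, dtype=np.float64)
        if not np.isfinite(self.h).all():
            raise ValueError("non-finite model parameters")

    @property
    def L(self) -> int:
        return self.h.shape[0]

    @property
    def q(self) -> int:
        return self.h.shape[1]

    @property
    def has_couplings(self) -> bool:
        return False

    def coupling_field(self, seq: np.ndarray, site: int) -> np.ndarray:
        return self.h[site]

    def as_potts(self) -> PottsModel:
        L, q = self.h.shape
        return PottsModel(self.h.copy(), np.zeros((L, L, q, q)), self.alphabet)


def _check_seq(model, seq) -> np.ndarray:
    if isinstance(seq, str):
        seq = model.alphabet.encode(seq)
    seq = np.asarray(seq)
    if seq.ndim != 1 or seq.shape[0] != model.L:
        raise ValueError(f"sequence length {seq.shape} does not match model L={model.L}")
    if seq.size and (seq.min() < 0 or seq.max() >= model.q):
        raise ValueError("sequence symbol outside the model alphabet")
    return seq.astype(np.intp)


def energy(model: PottsModel | ProfileModel, seq) -> float:
    """Statistical energy E(a) = -sum_i h_i(a_i) - sum_{i<j} J_ij(a_i,a_j)."""
    a = _check_seq(model, seq)
    e = -float(model.h[np.arange(model.L), a].sum())
    if model.has_couplings:
        idx = np.arange(model.L)
        pair = model.J[idx[:, None], idx[None, :], a[:, None], a[None, :]]
        e -= 0.5 * float(pair.sum())  # J_ii = 0; each i<j pair counted twice
    return e


def delta_energy(model: PottsModel | ProfileModel, seq, site: int, b: int | str) -> float:
    """Mutational effect dE = E(seq with site -> b) - E(seq), in O(L)."""
    a = _check_seq(model, seq)
    if not 0 <= site < model.L:
        raise ValueError(f"site {site} outside [0, {model.L})")
    if isinstance(b, str):
        b = model.alphabet.index(b)
    if not 0 <= b < model.q:
        raise ValueError(f"symbol index {b} outside the alphabet")
    f = model.coupling_field(a, site)
    return float(f[a[site]] - f[b])


def mutant_scan(model: PottsModel | ProfileModel, seq) -> np.ndarray:
    """Full single-mutant scan: (L, q-1) matrix of dE over non-gap targets.

    Column order follows the alphabet with the gap dropped.  Rows at gapped
    positions of `seq` are NaN (gaps are never mutated).
    """
    a = _check_seq(model, seq)
    gap = model.alphabet.gap_index
    if gap is None:
        raise ValueError("mutant_scan requires an alphabet with a gap symbol")
    targets = np.array([s for s in range(model.q) if s != gap])
    out = np.full((model.L, targets.size), np.nan)
    for i in range(model.L):
        if a[i] == gap:
            continue
        f = model.coupling_field(a, i)
        out[i] = f[a[i]] - f[targets]
    return out


def conditional_distribution(
    model: PottsModel | ProfileModel,
    seq,
    site: int,
    allowed,
    beta: float = 1.0,
) -> np.ndarray:
    """Substitution probabilities over an allowed symbol set.

    P(b) is proportional to exp{beta * [h_i(b) + sum_{j != i} J_ij(b, a_j)]}
    restricted to `allowed` (equivalently proportional to exp(-beta dE)).
    Stabilized by max-shift before exponentiation; beta=0 gives the uniform
    distribution over `allowed` (pure mutation accumulation, no selection).
    """
    a = _check_seq(model, seq)
    allowed = np.asarray(sorted(allowed), dtype=np.intp)
    if allowed.size == 0:
        raise ValueError("empty allowed set")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    f = model.coupling_field(a, site)[allowed]
    logit = beta * f
    logit -= logit.max()
    p = np.exp(logit)
    return p / p.sum()


def zero_sum_gauge(model: PottsModel) -> PottsModel:
    """Return the gauge-equivalent model with zero-sum fields and couplings.

    After the transform, sum_a h_i(a) = 0 and every row/column sum of each
    J_ij block is 0; all energy differences between sequences are unchanged.
    """
    J = model.J
    row = J.mean(axis=3, keepdims=True)   # mean over b
    col = J.mean(axis=2, keepdims=True)   # mean over a
    tot = J.mean(axis=(2, 3), keepdims=True)
    Jg = J - row - col + tot
    # field correction absorbs the per-site part of the coupling gauge
    h = model.h + (row - tot)[:, :, :, 0].sum(axis=1)
    hg = h - h.mean(axis=1, keepdims=True)
    return PottsModel(hg, Jg, model.alphabet)


def profile_from_msa(msa, weights=None, pseudocount: float = 0.01,
                     alphabet: Alphabet = PROTEIN) -> ProfileModel:
    """Fit a profile model h_i(a) = log f~_i(a) from an alignment.

    f~ is the (optionally weighted) empirical frequency mixed with the
    uniform distribution: f~ = (1 - pseudocount) f + pseudocount / q.
    """
    if isinstance(msa, np.ndarray):
        X = msa.astype(np.intp)
    else:
        X = alphabet.encode_msa(msa).astype(np.intp)
    if X.size == 0:
        raise ValueError("empty alignment")
    if not 0.0 <= pseudocount <= 1.0:
        raise ValueError("pseudocount must lie in [0, 1]")
    M, L = X.shape
    q = alphabet.q
    if weights is None:
        w = np.ones(M)
    else:
        w = np.asarray(weights, dtype=float)
        if w.shape != (M,):
            raise ValueError("weights length does not match alignment depth")
    f = np.zeros((L, q))
    for i in range(L):
        f[i] = np.bincount(X[:, i], weights=w, minlength=q)
    f /= w.sum()
    f = (1.0 - pseudocount) * f + pseudocount / q
    if pseudocount == 0.0 and (f == 0).any():
        warnings.warn("zero frequencies with pseudocount=0 give -inf fields; "
                      "clipping to a tiny floor", stacklevel=2)
        f = np.clip(f, 1e-300, None)
    return ProfileModel(np.log(f), alphabet)


# ---------------------------------------------------------------------------
# plain-text parameter format
#
# Lines are either "h i a value" or "J i j a b value" with 0-based integer
# indices over the fixed alphabet ordering.  Writing emits the strictly
# upper-triangular couplings (i < j); reading symmetrizes.  Unlisted entries
# are zero.
# ---------------------------------------------------------------------------

def write_params(path, model: PottsModel | ProfileModel) -> None:
    """Write a model to the plain-text parameter dialect (exact round trip)."""
    with open(path, "w") as fh:
        fh.write(f"# evoscape potts params L={model.L} q={model.q}\n")
        for i in range(model.L):
            for a in range(model.q):
                v = float(model.h[i, a])
                if v != 0.0:
                    fh.write(f"h {i} {a} {v!r}\n")
        if model.has_couplings:
            for i in range(model.L):
                for j in range(i + 1, model.L):
                    block = model.J[i, j]
                    if not block.any():
                        continue
                    for a in range(model.q):
                        for b in range(model.q):
                            v = float(block[a, b])
                            if v != 0.0:
                                fh.write(f"J {i} {j} {a} {b} {v!r}\n")


def read_params(path, L: int | None = None, q: int | None = None,
                alphabet: Alphabet = PROTEIN) -> PottsModel:
    """Read a model from the plain-text dialect; couplings are symmetrized.

    L and q default to the header line when present, else to the alphabet
    size and the largest index seen.  Missing entries are zero (a warning is
    logged when a file contains no coupling lines at all).
    """
    h_entries: list[tuple[int, int, float]] = []
    j_entries: list[tuple[int, int, int, int, float]] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line.split():
                    if tok.startswith("L="):
                        L = L or int(tok[2:])
                    elif tok.startswith("q="):
                        q = q or int(tok[2:])
                continue
            parts = line.split()
            try:
                if parts[0] == "h" and len(parts) == 4:
                    h_entries.append((int(parts[1]), int(parts[2]), float(parts[3])))
                elif parts[0] == "J" and len(parts) == 6:
                    j_entries.append((int(parts[1]), int(parts[2]),
                                      int(parts[3]), int(parts[4]), float(parts[5])))
                else:
                    raise ValueError
            except (ValueError, IndexError):
                raise ValueError(f"{path}: malformed line {ln}: {line!r}") from None
    if L is None:
        sites = [e[0] for e in h_entries] + [x for e in j_entries for x in e[:2]]
        if not sites:
            raise ValueError(f"{path}: cannot infer L from an empty file")
        L = max(sites) + 1
    if q is None:
        q = alphabet.q
    h = np.zeros((L, q))
    J = np.zeros((L, L, q, q))
    for i, a, v in h_entries:
        if not (0 <= i < L and 0 <= a < q):
            raise ValueError(f"{path}: h index ({i},{a}) out of range for L={L}, q={q}")
        h[i, a] = v
    for i, j, a, b, v in j_entries:
        if not (0 <= i < L and 0 <= j < L and 0 <= a < q and 0 <= b < q):
            raise ValueError(f"{path}: J index ({i},{j},{a},{b}) out of range")
        if i == j:
            raise ValueError(f"{path}: diagonal coupling J[{i},{i}] not allowed")
        J[i, j, a, b] = v
        J[j, i, b, a] = v
    if not j_entries:
        logger.warning("%s: no coupling lines; couplings filled as zero", path)
    alpha = alphabet if q == alphabet.q else Alphabet("".join(chr(48 + k) for k in range(q)), gap=None)
    return PottsModel(h, J, alpha)
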