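"""Synthetic landscapes with planted contacts, equilibrium samples, and a
toy Boltzmann-machine learner.

These generators make every other part of the package testable end to end
without external data: a sparse Potts landscape whose coupled pairs play the
role of structural contacts, an equilibrium alignment standing in for
naturally diverged homologs, and a low-energy wildtype with a codon
assignment from which experimental evolution can be launched.  The toy
Boltzmann-machine learner closes the inference -> simulation loop at small
L and is a test utility, not a production inference engine.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .alphabet import PROTEIN, Alphabet
from .codons import EvolvingState, assign_codons
from .contactmap import ContactMap
from .landscape import PottsModel, ProfileModel, profile_from_msa, zero_sum_gauge

__all__ = ["SyntheticLandscapeSpec", "random_potts", "gibbs_sample",
           "synthetic_wildtype", "toy_bm_learn", "toy_alphabet"]


def toy_alphabet(q: int) -> Alphabet:
    """A gapless q-letter alphabet for desk-scale models (q <= 21)."""
    if q == PROTEIN.q:
        return PROTEIN
    return Alphabet("ACDEFGHIKLMNPQRSTVWY"[:q], gap=None)


@dataclass
class SyntheticLandscapeSpec:
    """Recipe for a random sparse Potts landscape with planted contacts.

    Fields are i.i.d. Gaussian with sd `field_scale`; coupling blocks are
    Gaussian with sd `coupling_scale` and exist only on the planted edge
    set given by `topology`: ``random_graph`` (Erdos-Renyi with the given
    edge probability among pairs separated by at least `min_separation`),
    ``chain`` (nearest neighbors), or ``2d_lattice``.  The q=4 default is
    sized for fast tests, with scales chosen so single-mutant |dE| from a
    low-energy wildtype spans roughly [0, 4] — the dynamic range typical of
    deep-mutational-scan effect predictions; use q=21 (scales ~1) for
    codon-level integration studies.
    """

    L: int = 30
    q: int = 4
    topology: str = "random_graph"
    edge_prob: float = 0.08
    coupling_scale: float = 0.4
    field_scale: float = 0.75
    min_separation: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if self.coupling_scale < 0 or self.field_scale < 0:
            raise ValueError("scales must be >= 0")
        if self.topology not in ("random_graph", "chain", "2d_lattice"):
            raise ValueError(f"unknown topology {self.topology!r}")


def _planted_edges(spec: SyntheticLandscapeSpec, rng: np.random.Generator) -> list[tuple[int, int]]:
    L = spec.L
    if spec.topology == "chain":
        return [(i, i + 1) for i in range(L - 1)]
    if spec.topology == "2d_lattice":
        side = int(np.ceil(np.sqrt(L)))
        edges = []
        for i in range(L):
            r, c = divmod(i, side)
            for j in (i + 1, i + side):  # right and down neighbors
                if j < L and (j != i + 1 or c != side - 1):
                    edges.append((i, j))
        return edges
    edges = []
    for i in range(L):
        for j in range(i + spec.min_separation, L):
            if rng.random() < spec.edge_prob:
                edges.append((i, j))
    return edges


def random_potts(spec: SyntheticLandscapeSpec) -> tuple[PottsModel, ContactMap]:
    """Draw a landscape from the spec; returns the model and its planted map.

    The returned model is in the zero-sum gauge.  The contact map retains
    planted edges with |i - j| >= min_separation (for random graphs this is
    all of them), ready for PPV evaluation.
    """
    rng = np.random.default_rng(spec.seed)
    L, q = spec.L, spec.q
    alphabet = toy_alphabet(q)
    gap = alphabet.gap_index
    h = rng.normal(0.0, spec.field_scale, size=(L, q)) if spec.field_scale else np.zeros((L, q))
    J = np.zeros((L, L, q, q))
    edges = _planted_edges(spec, rng) if spec.coupling_scale > 0 else []
    for (i, j) in edges:
        block = rng.normal(0.0, spec.coupling_scale, size=(q, q))
        if gap is not None:
            # couplings act between amino acids; the gap state is neutral
            block[gap, :] = 0.0
            block[:, gap] = 0.0
        J[i, j] = block
        J[j, i] = block.T
    model = zero_sum_gauge(PottsModel(h, J, alphabet))
    contacts = {(i, j) for (i, j) in edges if abs(i - j) >= spec.min_separation}
    cmap = ContactMap(L=L, contacts=contacts, min_separation=spec.min_separation,
                      distance_cutoff=8.0)
    return model, cmap


@njit(cache=True)
def _gibbs_sweeps(state, h, J, n_sweeps, u):
    """Heat-bath sweeps over all sites; u has shape (n_sweeps, L)."""
    L, q = h.shape
    p = np.empty(q)
    for s in range(n_sweeps):
        for i in range(L):
            mx = -1e300
            for b in range(q):
                v = h[i, b]
                for j in range(L):
                    if j != i:
                        v += J[i, j, b, state[j]]
                p[b] = v
                if v > mx:
                    mx = v
            tot = 0.0
            for b in range(q):
                p[b] = np.exp(p[b] - mx)
                tot += p[b]
            r = u[s, i] * tot
            acc = 0.0
            sel = q - 1
            for b in range(q):
                acc += p[b]
                if r < acc:
                    sel = b
                    break
            state[i] = sel


def gibbs_sample(model: PottsModel | ProfileModel, n_sequences: int,
                 burn_in: int = 200, thinning: int = 10, seed: int = 0) -> np.ndarray:
    """Equilibrium sample of the landscape by single-site heat-bath sweeps.

    Returns an (n_sequences, L) int8 alignment drawn from P = exp(-E)/Z
    after `burn_in` full sweeps, keeping every `thinning`-th sweep.  Meant
    for desk-scale L*q; the chain mixes by random-scan-equivalent
    systematic sweeps.
    """
    rng = np.random.default_rng(seed)
    h = model.h
    J = model.J if model.has_couplings else np.zeros((model.L, model.L, model.q, model.q))
    state = rng.integers(model.q, size=model.L).astype(np.int8)
    _gibbs_sweeps(state, h, J, burn_in, rng.random((max(burn_in, 1), model.L)))
    out = np.empty((n_sequences, model.L), dtype=np.int8)
    for m in range(n_sequences):
        _gibbs_sweeps(state, h, J, thinning, rng.random((max(thinning, 1), model.L)))
        out[m] = state
    return out


def synthetic_wildtype(model: PottsModel | ProfileModel, seed: int = 0,
                       quench_sweeps: int = 3) -> EvolvingState:
    """A low-energy wildtype: greedy T -> 0 quench, then codon assignment.

    Coordinate-descent argmax sweeps from a random start.  The quench is
    truncated after `quench_sweeps` full sweeps so that the wildtype sits
    deep in the landscape (well below typical equilibrium energies) without
    being a strict local optimum — real wildtypes are highly fit but still
    improvable, which is what lets strong selection (T << 1) decrease
    energy further.  For a fields-only model one sweep already reaches the
    per-site argmax sequence.  For 21-state models the gap state is
    excluded so the wildtype is gapless; codons are then drawn uniformly
    among synonymous sense codons.
    """
    rng = np.random.default_rng(seed)
    gap = model.alphabet.gap_index
    allowed = np.array([s for s in range(model.q) if s != gap])
    seq = rng.choice(allowed, size=model.L).astype(np.intp)
    for _ in range(quench_sweeps):
        changed = False
        for i in rng.permutation(model.L):
            f = model.coupling_field(seq, i)[allowed]
            best = allowed[int(np.argmax(f))]
            if best != seq[i]:
                seq[i] = best
                changed = True
        if not changed:
            break
    if model.q == PROTEIN.q:
        return assign_codons(seq.astype(np.int8), mode="random_synonymous",
                             seed=int(rng.integers(2**31)))
    return EvolvingState(None, seq.astype(np.int8))  # toy alphabets: no codon layer


def toy_bm_learn(msa: np.ndarray, l2_penalty: float = 0.01, n_epochs: int = 100,
                 mc_samples: int = 500, seed: int = 0, learning_rate: float = 0.05,
                 pseudocount: float = 0.01, alphabet: Alphabet | None = None,
                 sweeps_per_epoch: int = 5) -> PottsModel:
    """Desk-scale Boltzmann-machine learning of a Potts model from an MSA.

    Gradient ascent on the l2-regularized likelihood, with model moments
    estimated from persistent Gibbs chains (PCD).  Guarded to small L and q;
    it exists to close the inference -> simulation loop in tests, not to
    train production landscapes.
    """
    X = np.asarray(msa, dtype=np.intp)
    M, L = X.shape
    q = int(X.max()) + 1 if alphabet is None else alphabet.q
    if L > 25 or q > 8:
        raise ValueError(f"toy learner is limited to L<=25, q<=8 (got L={L}, q={q})")
    alphabet = alphabet or toy_alphabet(q)
    rng = np.random.default_rng(seed)

    # pseudocounted data moments
    fi = np.zeros((L, q))
    for i in range(L):
        fi[i] = np.bincount(X[:, i], minlength=q)
    fi = (1 - pseudocount) * fi / M + pseudocount / q
    fij = np.zeros((L, L, q, q))
    one_hot = np.zeros((M, L, q))
    one_hot[np.arange(M)[:, None], np.arange(L)[None, :], X] = 1.0
    flat = one_hot.reshape(M, L * q)
    fij = (flat.T @ flat).reshape(L, q, L, q).transpose(0, 2, 1, 3) / M
    fij = (1 - pseudocount) * fij + pseudocount / q**2

    h = np.log(fi)
    h -= h.mean(axis=1, keepdims=True)
    J = np.zeros((L, L, q, q))
    if n_epochs == 0:
        return PottsModel(h, J, alphabet)

    chains = rng.integers(q, size=(mc_samples, L)).astype(np.int8)
    for _ in range(n_epochs):
        for c in range(mc_samples):
            _gibbs_sweeps(chains[c], h, J, sweeps_per_epoch,
                          rng.random((sweeps_per_epoch, L)))
        Xi = chains.astype(np.intp)
        gi = np.zeros((L, q))
        for i in range(L):
            gi[i] = np.bincount(Xi[:, i], minlength=q)
        gi /= mc_samples
        oh = np.zeros((mc_samples, L, q))
        oh[np.arange(mc_samples)[:, None], np.arange(L)[None, :], Xi] = 1.0
        gf = oh.reshape(mc_samples, L * q)
        gij = (gf.T @ gf).reshape(L, q, L, q).transpose(0, 2, 1, 3) / mc_samples
        h += learning_rate * (fi - gi - l2_penalty * h)
        gradJ = fij - gij - l2_penalty * J
        gradJ[np.arange(L), np.arange(L)] = 0.0
        J += learning_rate * 0.5 * (gradJ + gradJ.transpose(1, 0, 3, 2))
    return PottsModel(h, J, alphabet)
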