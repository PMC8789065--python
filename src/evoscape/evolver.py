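"""Mutation–selection Markov chain over coding sequences.

Each elementary step of the chain (i) picks a non-gap site uniformly at
random, (ii) draws a replacement amino acid b from the accessible set
A_acc(codon) with probability proportional to exp{-beta dE(a_i -> b)} —
selection acts on the amino acid sequence through the landscape, with
selection temperature T = 1/beta — and (iii) picks uniformly one of the
sense codons of b within one nucleotide of the current codon.  Stop codons
have zero proposal probability, gaps are frozen, and every step (including
synonymous and identity moves) counts as one Monte Carlo step, so the
amino acid Hamming distance from the starting sequence never exceeds the
step count.

T < 1 strengthens selection (the T -> 0 limit is greedy directed evolution,
implemented as an exact argmax with uniform tie-breaking); T > 1 weakens it
(beta -> 0 is mutation accumulation without selection).

A library is M independent chains initiated in the wildtype; snapshots of
all chains are emitted at requested step counts from the same long runs.
An auxiliary amino-acid-level mode ("seec") proposes all non-gap symbols
regardless of codon accessibility; at beta = 1 it is a random-scan Gibbs
sampler for the landscape's Boltzmann distribution and is used for
stationarity tests and for quantifying the effect of codon accessibility.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .alphabet import PROTEIN
from .codons import (
    ACC_AA,
    ACC_COUNT,
    CODONS_NEAR,
    CODONS_NEAR_COUNT,
    EvolvingState,
    accessible_amino_acids,
    codons_within_one,
)
from .landscape import PottsModel, ProfileModel, conditional_distribution, energy

__all__ = ["EvolverConfig", "Trajectory", "LibrarySnapshots",
           "evolution_step", "evolve_chain", "evolve_library", "subsample_msa"]

_ARGMAX_TOL = 1e-12


@dataclass
class EvolverConfig:
    """Simulation parameters of the evolutionary Markov chain.

    T is the selection temperature (beta = 1/T; T = 0 selects the greedy
    argmax limit), n_steps the number N_MC of mutational steps per chain,
    n_chains the library size M, and snapshot_steps the step counts at
    which chain states are recorded (default: final step only).
    """

    T: float = 1.0
    n_steps: int = 100
    n_chains: int = 1
    snapshot_steps: tuple[int, ...] | None = None
    seed: int = 0
    mode: str = "codon"

    def __post_init__(self) -> None:
        if self.T < 0:
            raise ValueError("selection temperature must be >= 0")
        if self.n_steps < 0 or self.n_chains < 1:
            raise ValueError("n_steps must be >= 0 and n_chains >= 1")
        if self.mode not in ("codon", "seec"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.snapshot_steps is None:
            self.snapshot_steps = (self.n_steps,)
        self.snapshot_steps = tuple(sorted(set(int(s) for s in self.snapshot_steps)))
        if self.snapshot_steps and not (
            0 <= self.snapshot_steps[0] and self.snapshot_steps[-1] <= self.n_steps
        ):
            raise ValueError("snapshot_steps must lie within [0, n_steps]")

    @property
    def beta(self) -> float:
        if self.T == 0:
            raise ValueError("T=0 is the argmax limit; beta is undefined")
        return 0.0 if np.isinf(self.T) else 1.0 / self.T


@dataclass
class Trajectory:
    """Snapshots of a single chain with per-step distance/energy traces."""

    steps: np.ndarray                 # snapshot step indices
    states: list[EvolvingState]       # snapshot states (codon mode)
    distances: np.ndarray             # Hamming distance to wildtype, per step 0..n
    energies: np.ndarray              # statistical energy, per step 0..n

    @property
    def snapshot_distances(self) -> np.ndarray:
        return self.distances[self.steps]

    @property
    def snapshot_energies(self) -> np.ndarray:
        return self.energies[self.steps]


@dataclass
class LibrarySnapshots:
    """Libraries of M chains recorded at a set of step counts.

    ``aa[s]`` is the (M, L) amino acid index alignment at snapshot step s;
    ``codons[s]`` the matching codon index arrays (codon mode only).
    ``mean_distance`` / ``mean_energy`` trace the across-chain means at
    every step of the underlying long runs.
    """

    steps: tuple[int, ...]
    aa: dict[int, np.ndarray]
    codons: dict[int, np.ndarray] = field(default_factory=dict)
    distances: dict[int, np.ndarray] = field(default_factory=dict)
    energies: dict[int, np.ndarray] = field(default_factory=dict)
    mean_distance: np.ndarray | None = None
    mean_energy: np.ndarray | None = None
    config: EvolverConfig | None = None

    def msa(self, step: int | None = None) -> np.ndarray:
        if step is None:
            step = self.steps[-1]
        return self.aa[step]

    def sequences(self, step: int | None = None) -> list[str]:
        return [PROTEIN.decode(row) for row in self.msa(step)]


# ---------------------------------------------------------------------------
# numba kernels
# ---------------------------------------------------------------------------

@njit(cache=True)
def _run_codon_chain(codons, aa, wt_aa, h, J, beta, argmax, mutable, u,
                     acc_aa, acc_count, near, near_count,
                     dist, ener, snap_steps, snap_aa, snap_codons):
    L = aa.shape[0]
    n_steps = u.shape[0]
    n_mut = mutable.shape[0]
    d = 0
    for i in range(L):
        if aa[i] != wt_aa[i]:
            d += 1
    e = ener[0]
    dist[0] = d
    p = 0
    if p < snap_steps.shape[0] and snap_steps[p] == 0:
        snap_aa[p] = aa
        snap_codons[p] = codons
        p += 1
    logits = np.empty(8)
    for t in range(n_steps):
        i = mutable[min(int(u[t, 0] * n_mut), n_mut - 1)]
        c = codons[i]
        cnt = acc_count[c]
        cur = aa[i]
        cur_pos = 0
        for m in range(cnt):
            b = acc_aa[c, m]
            s = h[i, b]
            for j in range(L):
                if j != i:
                    s += J[i, j, b, aa[j]]
            logits[m] = s
            if b == cur:
                cur_pos = m
        if argmax:
            best = logits[0]
            for m in range(1, cnt):
                if logits[m] > best:
                    best = logits[m]
            tol = _ARGMAX_TOL * max(1.0, abs(best))
            n_best = 0
            for m in range(cnt):
                if logits[m] >= best - tol:
                    n_best += 1
            pick = min(int(u[t, 1] * n_best), n_best - 1)
            sel = 0
            for m in range(cnt):
                if logits[m] >= best - tol:
                    if pick == 0:
                        sel = m
                        break
                    pick -= 1
        else:
            mx = logits[0]
            for m in range(1, cnt):
                if logits[m] > mx:
                    mx = logits[m]
            tot = 0.0
            for m in range(cnt):
                logits[m] = np.exp(beta * (logits[m] - mx))
                tot += logits[m]
            r = u[t, 1] * tot
            acc = 0.0
            sel = cnt - 1
            for m in range(cnt):
                acc += logits[m]
                if r < acc:
                    sel = m
                    break
        b = acc_aa[c, sel]
        k2 = near_count[c, b]
        codons[i] = near[c, b, min(int(u[t, 2] * k2), k2 - 1)]
        if b != cur:
            # recompute the two local fields for the energy update
            s_cur = h[i, cur]
            s_new = h[i, b]
            for j in range(L):
                if j != i:
                    s_cur += J[i, j, cur, aa[j]]
                    s_new += J[i, j, b, aa[j]]
            e += s_cur - s_new
            if cur == wt_aa[i]:
                d += 1
            elif b == wt_aa[i]:
                d -= 1
            aa[i] = b
        dist[t + 1] = d
        ener[t + 1] = e
        if p < snap_steps.shape[0] and snap_steps[p] == t + 1:
            snap_aa[p] = aa
            snap_codons[p] = codons
            p += 1


@njit(cache=True)
def _run_seec_chain(aa, wt_aa, h, J, beta, argmax, mutable, states, u,
                    dist, ener, snap_steps, snap_aa):
    L = aa.shape[0]
    n_steps = u.shape[0]
    n_mut = mutable.shape[0]
    n_states = states.shape[0]
    d = 0
    for i in range(L):
        if aa[i] != wt_aa[i]:
            d += 1
    e = ener[0]
    dist[0] = d
    p = 0
    if p < snap_steps.shape[0] and snap_steps[p] == 0:
        snap_aa[p] = aa
        p += 1
    logits = np.empty(n_states)
    for t in range(n_steps):
        i = mutable[min(int(u[t, 0] * n_mut), n_mut - 1)]
        cur = aa[i]
        for m in range(n_states):
            b = states[m]
            s = h[i, b]
            for j in range(L):
                if j != i:
                    s += J[i, j, b, aa[j]]
            logits[m] = s
        if argmax:
            best = logits[0]
            for m in range(1, n_states):
                if logits[m] > best:
                    best = logits[m]
            tol = _ARGMAX_TOL * max(1.0, abs(best))
            n_best = 0
            for m in range(n_states):
                if logits[m] >= best - tol:
                    n_best += 1
            pick = min(int(u[t, 1] * n_best), n_best - 1)
            sel = 0
            for m in range(n_states):
                if logits[m] >= best - tol:
                    if pick == 0:
                        sel = m
                        break
                    pick -= 1
        else:
            mx = logits[0]
            for m in range(1, n_states):
                if logits[m] > mx:
                    mx = logits[m]
            tot = 0.0
            for m in range(n_states):
                logits[m] = np.exp(beta * (logits[m] - mx))
                tot += logits[m]
            r = u[t, 1] * tot
            acc = 0.0
            sel = n_states - 1
            for m in range(n_states):
                acc += logits[m]
                if r < acc:
                    sel = m
                    break
        b = states[sel]
        if b != cur:
            s_cur = h[i, cur]
            s_new = h[i, b]
            for j in range(L):
                if j != i:
                    s_cur += J[i, j, cur, aa[j]]
                    s_new += J[i, j, b, aa[j]]
            e += s_cur - s_new
            if cur == wt_aa[i]:
                d += 1
            elif b == wt_aa[i]:
                d -= 1
            aa[i] = b
        dist[t + 1] = d
        ener[t + 1] = e
        if p < snap_steps.shape[0] and snap_steps[p] == t + 1:
            snap_aa[p] = aa
            p += 1


def _as_potts_arrays(model: PottsModel | ProfileModel):
    if model.has_couplings:
        return model.h, model.J
    L, q = model.h.shape
    return model.h, np.zeros((L, L, q, q))


def _mutable_sites(aa: np.ndarray, gap_index) -> np.ndarray:
    if gap_index is None:
        mutable = np.arange(aa.shape[0], dtype=np.int64)
    else:
        mutable = np.nonzero(aa != gap_index)[0].astype(np.int64)
    if mutable.size == 0:
        raise ValueError("all-gap sequence: no mutable site")
    return mutable


def _seec_states(model) -> np.ndarray:
    gap = model.alphabet.gap_index
    return np.array([s for s in range(model.q) if s != gap], dtype=np.int64)


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def evolution_step(state: EvolvingState, model: PottsModel | ProfileModel,
                   beta: float, rng: np.random.Generator) -> EvolvingState:
    """One step of the codon-level chain (reference implementation).

    This is the plain-Python counterpart of the compiled kernel, convenient
    for unit-level checks of the selection probabilities; libraries should
    be generated with :func:`evolve_library`.
    """
    new = state.copy()
    mutable = _mutable_sites(new.aa, PROTEIN.gap_index)
    i = int(rng.choice(mutable))
    from .codons import CODONS, codon_index  # local to avoid cycles at import

    codon = CODONS[new.codons[i]]
    acc = sorted(PROTEIN.index(a) for a in accessible_amino_acids(codon))
    probs = conditional_distribution(model, new.aa, i, acc, beta)
    b = int(rng.choice(acc, p=probs))
    options = sorted(codons_within_one(codon, PROTEIN.symbols[b]))
    new_codon = options[int(rng.integers(len(options)))]
    new.codons[i] = codon_index(new_codon)
    new.aa[i] = b
    return new


def _chain_uniforms(seed_seq: np.random.SeedSequence, n_steps: int) -> np.ndarray:
    return np.random.default_rng(seed_seq).random((n_steps, 3))


def evolve_chain(wildtype: EvolvingState, model: PottsModel | ProfileModel,
                 config: EvolverConfig) -> Trajectory:
    """Run a single chain; snapshots at ``config.snapshot_steps``."""
    lib = evolve_library(wildtype, model, config if config.n_chains == 1 else
                         EvolverConfig(config.T, config.n_steps, 1,
                                       config.snapshot_steps, config.seed, config.mode))
    states = []
    for s in lib.steps:
        if config.mode == "codon":
            states.append(EvolvingState(lib.codons[s][0], lib.aa[s][0]))
    return Trajectory(
        steps=np.array(lib.steps),
        states=states,
        distances=lib._dist_traj[0],
        energies=lib._ener_traj[0],
    )


def evolve_library(wildtype: EvolvingState, model: PottsModel | ProfileModel,
                   config: EvolverConfig) -> LibrarySnapshots:
    """Simulate M independent chains from the wildtype; snapshot libraries.

    Chains use independent RNG streams spawned from ``config.seed``, so the
    result is reproducible and snapshots at increasing step counts reuse the
    same long runs.
    """
    if config.mode == "codon":
        if model.q != PROTEIN.q:
            raise ValueError("codon-mode evolution requires a 21-state landscape")
        if wildtype.codons is None:
            raise ValueError("codon-mode evolution requires a wildtype with a "
                             "nucleotide layer (see assign_codons)")
    h, J = _as_potts_arrays(model)
    wt_aa = np.asarray(wildtype.aa, dtype=np.int8)
    mutable = _mutable_sites(wt_aa, model.alphabet.gap_index)
    e0 = energy(model, wt_aa.astype(np.intp))
    M, n = config.n_chains, config.n_steps
    snap_steps = np.asarray(config.snapshot_steps, dtype=np.int64)
    n_snap = snap_steps.shape[0]
    L = wt_aa.shape[0]

    snap_aa = np.empty((n_snap, M, L), dtype=np.int8)
    snap_codons = np.empty((n_snap, M, L), dtype=np.int8)
    dist_traj = np.empty((M, n + 1), dtype=np.int32)
    ener_traj = np.empty((M, n + 1), dtype=np.float64)

    children = np.random.SeedSequence(config.seed).spawn(M)
    argmax = config.T == 0
    beta = 0.0 if (argmax or np.isinf(config.T)) else 1.0 / config.T
    states = _seec_states(model)
    for m in range(M):
        u = _chain_uniforms(children[m], n)
        ener_traj[m, 0] = e0
        if config.mode == "codon":
            codons = wildtype.codons.astype(np.int8).copy()
            aa = wt_aa.copy()
            _run_codon_chain(codons, aa, wt_aa, h, J, beta, argmax, mutable, u,
                             ACC_AA, ACC_COUNT, CODONS_NEAR, CODONS_NEAR_COUNT,
                             dist_traj[m], ener_traj[m], snap_steps,
                             snap_aa[:, m], snap_codons[:, m])
        else:
            aa = wt_aa.copy()
            _run_seec_chain(aa, wt_aa, h, J, beta, argmax, mutable, states, u,
                            dist_traj[m], ener_traj[m], snap_steps, snap_aa[:, m])

    lib = LibrarySnapshots(
        steps=tuple(int(s) for s in snap_steps),
        aa={int(s): snap_aa[k] for k, s in enumerate(snap_steps)},
        codons={int(s): snap_codons[k] for k, s in enumerate(snap_steps)}
        if config.mode == "codon" else {},
        distances={int(s): dist_traj[:, s].copy() for s in snap_steps},
        energies={int(s): ener_traj[:, s].copy() for s in snap_steps},
        mean_distance=dist_traj.mean(axis=0),
        mean_energy=ener_traj.mean(axis=0),
        config=config,
    )
    lib._dist_traj = dist_traj
    lib._ener_traj = ener_traj
    return lib


def subsample_msa(msa: np.ndarray, size: int, seed: int = 0) -> np.ndarray:
    """Subsample `size` rows without replacement (seeded)."""
    M = msa.shape[0]
    if size > M:
        raise ValueError(f"cannot subsample {size} from {M} sequences")
    rng = np.random.default_rng(seed)
    idx = rng.choice(M, size=size, replace=False)
    return msa[idx]
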