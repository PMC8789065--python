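import numpy as np
import pytest

from evoscape.alphabet import PROTEIN
from evoscape.codons import EvolvingState, assign_codons
from evoscape.evolver import (EvolverConfig, evolution_step, evolve_chain,
                              evolve_library, subsample_msa)
from evoscape.landscape import PottsModel, ProfileModel, conditional_distribution
from evoscape.synthgen import SyntheticLandscapeSpec, random_potts, synthetic_wildtype


@pytest.fixture(scope="module")
def small21():
    spec = SyntheticLandscapeSpec(L=8, q=21, edge_prob=0.3, min_separation=1,
                                  coupling_scale=1.0, field_scale=1.0, seed=4)
    model, _ = random_potts(spec)
    wt = synthetic_wildtype(model, seed=5)
    return model, wt


class TestConfig:
    def test_validation(self):
        with pytest.raises(ValueError):
            EvolverConfig(T=-1)
        with pytest.raises(ValueError):
            EvolverConfig(n_steps=10, snapshot_steps=(20,))
        with pytest.raises(ValueError):
            EvolverConfig(mode="codons")

    def test_beta(self):
        assert EvolverConfig(T=2.0).beta == 0.5
        assert EvolverConfig(T=np.inf).beta == 0.0
        with pytest.raises(ValueError):
            EvolverConfig(T=0.0).beta


class TestEvolveLibrary:
    def test_zero_steps_returns_wildtype_copies(self, small21):
        model, wt = small21
        lib = evolve_library(wt, model, EvolverConfig(T=1, n_steps=0,
                                                      n_chains=5, seed=0))
        assert (lib.aa[0] == wt.aa[None, :]).all()
        assert (lib.distances[0] == 0).all()

    def test_same_seed_identical(self, small21):
        model, wt = small21
        cfg = EvolverConfig(T=1.0, n_steps=50, n_chains=10, seed=42)
        a = evolve_library(wt, model, cfg)
        b = evolve_library(wt, model, cfg)
        assert (a.aa[50] == b.aa[50]).all()
        assert (a.codons[50] == b.codons[50]).all()

    def test_consistency_and_distance_bound(self, small21):
        model, wt = small21
        steps = (0, 10, 40, 80)
        lib = evolve_library(wt, model, EvolverConfig(
            T=1.5, n_steps=80, n_chains=20, snapshot_steps=steps, seed=3))
        for s in steps:
            for m in range(20):
                EvolvingState(lib.codons[s][m], lib.aa[s][m])  # validates
            assert (lib.distances[s] <= s).all()

    def test_gaps_frozen(self):
        spec = SyntheticLandscapeSpec(L=6, q=21, edge_prob=0.3,
                                      min_separation=1, coupling_scale=1.0,
                                      field_scale=1.0, seed=9)
        model, _ = random_potts(spec)
        aa = "A-CD-E"
        wt = assign_codons(aa, seed=1)
        lib = evolve_library(wt, model, EvolverConfig(T=2.0, n_steps=200,
                                                      n_chains=10, seed=2))
        final = lib.aa[200]
        gap = PROTEIN.gap_index
        assert (final[:, 1] == gap).all() and (final[:, 4] == gap).all()
        assert (final[:, [0, 2, 3, 5]] != gap).all()

    def test_argmax_retention_fields_only(self):
        # wildtype at the strict per-site field optimum never substitutes at T=0
        rng = np.random.default_rng(6)
        h = rng.normal(size=(10, 21))
        h[:, PROTEIN.gap_index] = -50.0
        model = ProfileModel(h)
        best = h.argmax(axis=1).astype(np.int8)
        wt = assign_codons(best, seed=0)
        lib = evolve_library(wt, model, EvolverConfig(T=0.0, n_steps=300,
                                                      n_chains=5, seed=1))
        assert (lib.aa[300] == best[None, :]).all()

    def test_mean_distance_nondecreasing_in_steps(self, small21):
        model, wt = small21
        lib = evolve_library(wt, model, EvolverConfig(T=1.0, n_steps=200,
                                                      n_chains=500, seed=8))
        md = lib.mean_distance
        # nondecreasing across checkpoints, up to saturation-level noise
        checkpoints = md[[0, 10, 25, 50, 100, 200]]
        assert (np.diff(checkpoints) > -0.1).all()
        assert md[-1] > md[0]

    def test_all_gap_raises(self):
        spec = SyntheticLandscapeSpec(L=3, q=21, seed=0)
        model, _ = random_potts(spec)
        wt = assign_codons("---", seed=0)
        with pytest.raises(ValueError, match="no mutable site"):
            evolve_library(wt, model, EvolverConfig(T=1, n_steps=1, n_chains=1))

    def test_seec_mode_on_toy_alphabet(self):
        spec = SyntheticLandscapeSpec(L=5, q=4, topology="chain", seed=2)
        model, _ = random_potts(spec)
        wt = synthetic_wildtype(model, seed=3)
        lib = evolve_library(wt, model, EvolverConfig(T=1.0, n_steps=100,
                                                      n_chains=10, seed=4,
                                                      mode="seec"))
        assert lib.aa[100].shape == (10, 5)
        assert lib.aa[100].max() < 4


class TestEvolutionStep:
    def test_single_step_changes_at_most_one_codon(self, small21):
        model, wt = small21
        rng = np.random.default_rng(0)
        for _ in range(50):
            new = evolution_step(wt, model, beta=1.0, rng=rng)
            changed = (new.codons != wt.codons).sum()
            assert changed <= 1
            new.validate()

    def test_empirical_frequencies_match_conditional(self, small21):
        """Kernel one-step selection frequencies agree with the reference
        python implementation and hence with the closed-form conditional."""
        model, wt = small21
        n = 20_000
        lib = evolve_library(wt, model, EvolverConfig(T=1.0, n_steps=1,
                                                      n_chains=n, seed=11))
        rng = np.random.default_rng(12)
        ref = np.stack([evolution_step(wt, model, 1.0, rng).aa
                        for _ in range(n)])
        f_kernel = (lib.aa[1] != wt.aa[None, :]).mean(axis=0)
        f_ref = (ref != wt.aa[None, :]).mean(axis=0)
        # per-site substitution probabilities agree within 4 sigma
        se = np.sqrt(f_ref * (1 - f_ref) / n + f_kernel * (1 - f_kernel) / n)
        assert (np.abs(f_kernel - f_ref) < 4 * np.maximum(se, 1e-4)).all()


class TestTrajectoryAndSubsample:
    def test_trajectory_monotone_steps(self, small21):
        model, wt = small21
        traj = evolve_chain(wt, model, EvolverConfig(
            T=1.0, n_steps=60, n_chains=1, snapshot_steps=(0, 30, 60), seed=5))
        assert (np.diff(traj.steps) > 0).all()
        assert (traj.distances <= np.arange(61)).all()
        assert len(traj.states) == 3

    def test_subsample_without_replacement(self):
        msa = np.arange(50).reshape(10, 5)
        sub = subsample_msa(msa, 6, seed=0)
        assert sub.shape == (6, 5)
        assert len({tuple(r) for r in sub}) == 6
        with pytest.raises(ValueError):
            subsample_msa(msa, 11)


class TestAccessibilityShapesSpectra:
    def test_inaccessible_amino_acids_absent_in_codon_mode_only(self, planted):
        """After one mutational step, codon-mode libraries leave
        codon-inaccessible amino acids at exactly zero frequency, while the
        amino-acid-level (SEEC) chain populates them.  (Beyond one step the
        zero is no longer exact: a site can hop through an intermediate
        codon.)"""
        from evoscape.codons import ACC_AA, ACC_COUNT
        from evoscape.libstats import site_frequencies
        model, _, wt = planted
        mask = np.zeros((wt.L, 21), dtype=bool)  # accessible-from-wildtype
        for i, k in enumerate(wt.codons):
            for a in ACC_AA[k, : ACC_COUNT[k]]:
                mask[i, a] = True
        codon_lib = evolve_library(wt, model, EvolverConfig(
            T=2.0, n_steps=1, n_chains=800, seed=17))
        seec_lib = evolve_library(wt, model, EvolverConfig(
            T=2.0, n_steps=1, n_chains=800, seed=17, mode="seec"))
        f_codon = site_frequencies(codon_lib.msa(), q=21).values
        f_seec = site_frequencies(seec_lib.msa(), q=21).values
        assert f_codon[~mask].max() == 0.0
        assert (f_seec[~mask] > 0).sum() > 10
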