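import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr

from evoscape.landscape import ProfileModel, energy, profile_from_msa
from evoscape.synthgen import (SyntheticLandscapeSpec, gibbs_sample,
                               random_potts, synthetic_wildtype, toy_alphabet,
                               toy_bm_learn)


class TestRandomPotts:
    def test_zero_coupling_scale(self):
        spec = SyntheticLandscapeSpec(L=10, q=4, coupling_scale=0.0, seed=0)
        model, cmap = random_potts(spec)
        assert not model.J.any()
        assert len(cmap) == 0

    def test_seed_determinism(self):
        spec = SyntheticLandscapeSpec(seed=5)
        m1, c1 = random_potts(spec)
        m2, c2 = random_potts(spec)
        assert (m1.h == m2.h).all() and (m1.J == m2.J).all()
        assert c1.contacts == c2.contacts

    def test_couplings_only_on_planted_edges(self):
        spec = SyntheticLandscapeSpec(L=20, q=4, seed=1)
        model, cmap = random_potts(spec)
        norms = np.linalg.norm(model.J, axis=(2, 3))
        for i in range(20):
            for j in range(i + 1, 20):
                if (i, j) in cmap:
                    assert norms[i, j] > 0.1
                else:
                    assert norms[i, j] < 1e-10

    def test_zero_sum_gauge(self):
        model, _ = random_potts(SyntheticLandscapeSpec(seed=2))
        assert np.abs(model.h.sum(axis=1)).max() < 1e-10
        assert np.abs(model.J.sum(axis=2)).max() < 1e-10

    def test_chain_topology(self):
        spec = SyntheticLandscapeSpec(L=6, q=3, topology="chain", seed=3)
        model, cmap = random_potts(spec)
        norms = np.linalg.norm(model.J, axis=(2, 3))
        assert all(norms[i, i + 1] > 0 for i in range(5))
        assert len(cmap) == 0  # nearest neighbors fail the separation filter


class TestGibbsSample:
    def test_uniform_for_zero_model(self):
        q, L, n = 4, 5, 10_000
        model = ProfileModel(np.zeros((L, q)), toy_alphabet(q))
        msa = gibbs_sample(model, n, burn_in=10, thinning=1, seed=0)
        f = np.stack([np.bincount(msa[:, i], minlength=q) for i in range(L)]) / n
        z = (f - 1 / q) / np.sqrt((1 / q) * (1 - 1 / q) / n)
        assert (np.abs(z) < 3).mean() > 0.95
        assert np.abs(z).max() < 4.5

    def test_matches_enumeration_at_small_size(self):
        spec = SyntheticLandscapeSpec(L=3, q=3, topology="chain",
                                      coupling_scale=0.5, field_scale=0.5,
                                      seed=4)
        model, _ = random_potts(spec)
        states = np.array(list(itertools.product(range(3), repeat=3)))
        e = np.array([energy(model, s) for s in states])
        p = np.exp(-(e - e.min()))
        p /= p.sum()
        msa = gibbs_sample(model, 20_000, burn_in=100, thinning=2, seed=5)
        codes = msa[:, 0] * 9 + msa[:, 1] * 3 + msa[:, 2]
        emp = np.bincount(codes.astype(int), minlength=27) / len(codes)
        assert 0.5 * np.abs(emp - p).sum() < 0.02

    def test_seeded_reproducibility(self):
        model, _ = random_potts(SyntheticLandscapeSpec(L=6, q=4, seed=6))
        a = gibbs_sample(model, 20, seed=7)
        b = gibbs_sample(model, 20, seed=7)
        assert (a == b).all()


class TestSyntheticWildtype:
    def test_fields_only_gives_argmax(self):
        rng = np.random.default_rng(8)
        h = rng.normal(size=(12, 4))
        model = ProfileModel(h, toy_alphabet(4))
        wt = synthetic_wildtype(model, seed=9)
        assert (wt.aa == h.argmax(axis=1)).all()

    def test_energy_below_equilibrium_median(self, planted):
        model, _, wt = planted
        eq = gibbs_sample(model, 200, burn_in=200, thinning=5, seed=10)
        eq_e = np.median([energy(model, s.astype(int)) for s in eq])
        assert energy(model, wt.aa.astype(int)) < eq_e

    def test_protein_wildtype_has_codons(self, planted):
        _, _, wt = planted
        wt.validate()
        assert wt.codons is not None
        assert len(wt.dna) == 3 * wt.L

    def test_seed_determinism(self, planted):
        model, _, _ = planted
        a = synthetic_wildtype(model, seed=11)
        b = synthetic_wildtype(model, seed=11)
        assert (a.aa == b.aa).all() and (a.codons == b.codons).all()


class TestToyBmLearn:
    def test_zero_epochs_returns_profile_init(self):
        rng = np.random.default_rng(12)
        msa = rng.integers(3, size=(200, 6))
        model = toy_bm_learn(msa, n_epochs=0)
        assert not model.J.any()
        prof = profile_from_msa(msa, pseudocount=0.01,
                                alphabet=toy_alphabet(3))
        centered = prof.h - prof.h.mean(axis=1, keepdims=True)
        assert np.allclose(model.h, centered, atol=1e-10)

    def test_scale_guard(self):
        with pytest.raises(ValueError, match="limited"):
            toy_bm_learn(np.zeros((10, 30), dtype=int))

    def test_moment_matching_and_field_recovery(self):
        """Learning from a fields-only sample recovers field ranks and
        matches one-site marginals; couplings stay near the regularization
        floor."""
        rng = np.random.default_rng(13)
        L, q, M = 10, 4, 5000
        h_true = rng.normal(size=(L, q))
        truth = ProfileModel(h_true, toy_alphabet(q))
        msa = gibbs_sample(truth, M, burn_in=5, thinning=1, seed=14)
        model = toy_bm_learn(msa, l2_penalty=0.01, n_epochs=60,
                             mc_samples=400, seed=15, learning_rate=0.1)
        # fitted one-site marginals vs data marginals
        fi_data = np.stack([np.bincount(msa[:, i], minlength=q)
                            for i in range(L)]) / M
        sample = gibbs_sample(model, 4000, burn_in=50, thinning=1, seed=16)
        fi_model = np.stack([np.bincount(sample[:, i], minlength=q)
                             for i in range(L)]) / 4000
        assert np.abs(fi_model - fi_data).max() < 0.04
        h_c = h_true - h_true.mean(axis=1, keepdims=True)
        g_c = model.h - model.h.mean(axis=1, keepdims=True)
        rho = spearmanr(h_c.ravel(), g_c.ravel()).statistic
        assert rho > 0.9
        assert np.abs(model.J).max() < 0.5


class TestEndToEndLoop:
    def test_inference_simulation_loop_recovers_contacts(self):
        """Landscape -> equilibrium sample -> toy learner -> contact scores:
        planted couplings stay detectable through the full loop."""
        from evoscape.contacts import gauss_dca_scores, ppv
        spec = SyntheticLandscapeSpec(L=16, q=4, edge_prob=0.15,
                                      coupling_scale=1.0, field_scale=0.5,
                                      seed=17)
        model, cmap = random_potts(spec)
        if len(cmap) < 2:
            pytest.skip("unlucky topology draw")
        msa = gibbs_sample(model, 3000, burn_in=300, thinning=3, seed=18)
        learned = toy_bm_learn(msa, l2_penalty=0.005, n_epochs=40,
                               mc_samples=300, seed=19, learning_rate=0.1)
        # score pairs by the Frobenius norm of learned coupling blocks
        from evoscape.contacts import ScoreMatrix, apc_correction
        norms = np.linalg.norm(learned.J, axis=(2, 3))
        scores = apc_correction(ScoreMatrix(norms))
        assert ppv(scores, cmap, len(cmap)) > 2.5 * cmap.density
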