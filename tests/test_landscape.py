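import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from evoscape.alphabet import PROTEIN, Alphabet
from evoscape.landscape import (PottsModel, ProfileModel,
                                conditional_distribution, delta_energy,
                                energy, mutant_scan, profile_from_msa,
                                read_params, write_params, zero_sum_gauge)
from evoscape.synthgen import gibbs_sample

from conftest import make_random_model


def brute_force_energy(model, seq):
    e = 0.0
    for i in range(model.L):
        e -= model.h[i, seq[i]]
        for j in range(i + 1, model.L):
            e -= model.J[i, j, seq[i], seq[j]]
    return e


class TestEnergy:
    def test_zero_model_gives_zero(self):
        model = PottsModel(np.zeros((4, 3)), np.zeros((4, 4, 3, 3)),
                           Alphabet("ABC", gap=None))
        assert energy(model, np.array([0, 1, 2, 1])) == 0.0

    def test_toy_hand_value(self, toy2_model):
        # -h_0(B) - J_01(B,C) = -1 - 0.5
        assert energy(toy2_model, np.array([1, 2])) == pytest.approx(-1.5)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce(self, seed):
        model = make_random_model(seed, L=6, q=4)
        rng = np.random.default_rng(seed + 100)
        for _ in range(20):
            seq = rng.integers(4, size=6)
            assert energy(model, seq) == pytest.approx(
                brute_force_energy(model, seq), abs=1e-10)

    def test_length_and_symbol_errors(self, toy2_model):
        with pytest.raises(ValueError):
            energy(toy2_model, np.array([0, 1, 2]))
        with pytest.raises(ValueError):
            energy(toy2_model, np.array([0, 5]))


class TestDeltaEnergy:
    def test_identity_mutation_is_zero(self, toy2_model):
        assert delta_energy(toy2_model, np.array([1, 2]), 0, 1) == 0.0

    def test_toy_hand_value(self, toy2_model):
        # site 0: B -> A removes both the field and the coupling
        assert delta_energy(toy2_model, np.array([1, 2]), 0, 0) == pytest.approx(1.5)

    @pytest.mark.parametrize("seed", range(3))
    def test_matches_full_energy_difference(self, seed):
        model = make_random_model(seed, L=7, q=5)
        rng = np.random.default_rng(seed)
        for _ in range(100):
            seq = rng.integers(5, size=7)
            site = int(rng.integers(7))
            b = int(rng.integers(5))
            mut = seq.copy()
            mut[site] = b
            assert delta_energy(model, seq, site, b) == pytest.approx(
                energy(model, mut) - energy(model, seq), abs=1e-10)


class TestMutantScan:
    def test_wildtype_column_zero_and_gap_rows_nan(self):
        rng = np.random.default_rng(0)
        h = rng.normal(size=(4, 21))
        model = PottsModel(h, np.zeros((4, 4, 21, 21)))
        seq = PROTEIN.encode("A-CD")
        scan = mutant_scan(model, seq)
        assert np.isnan(scan[1]).all()
        targets = [s for s in range(21) if s != PROTEIN.gap_index]
        for i in (0, 2, 3):
            k = targets.index(seq[i])
            assert scan[i, k] == 0.0

    def test_profile_rows_context_independent(self):
        rng = np.random.default_rng(1)
        model = ProfileModel(rng.normal(size=(5, 21)))
        s1 = PROTEIN.encode("ACDEF")
        s2 = PROTEIN.encode("WYFHK")
        m1, m2 = mutant_scan(model, s1), mutant_scan(model, s2)
        # rows differ only through the wildtype offset h_i(a_i)
        for i in range(5):
            shift = model.h[i, s1[i]] - model.h[i, s2[i]]
            assert np.allclose(m1[i] - m2[i], shift)

    def test_agrees_with_delta_energy(self):
        model = make_random_model(7, L=4, q=21)
        model = PottsModel(model.h, model.J)  # protein alphabet
        seq = PROTEIN.encode("ACDE")
        scan = mutant_scan(model, seq)
        targets = [s for s in range(21) if s != PROTEIN.gap_index]
        for i in range(4):
            for k, b in enumerate(targets):
                assert scan[i, k] == pytest.approx(
                    delta_energy(model, seq, i, b), abs=1e-12)


class TestConditionalDistribution:
    def test_beta_zero_uniform(self, toy2_model):
        p = conditional_distribution(toy2_model, np.array([1, 2]), 0,
                                     [0, 1, 2], beta=0.0)
        assert np.allclose(p, 1 / 3)

    def test_singleton(self, toy2_model):
        p = conditional_distribution(toy2_model, np.array([1, 2]), 0, [2], beta=1.0)
        assert p == pytest.approx([1.0])

    def test_toy_hand_normalized(self, toy2_model):
        # site 0 with context C at site 1: scores h+J = (0, 1.5, 0)
        p = conditional_distribution(toy2_model, np.array([1, 2]), 0,
                                     [0, 1, 2], beta=1.0)
        w = np.exp([0.0, 1.5, 0.0])
        assert np.allclose(p, w / w.sum(), atol=1e-12)

    def test_empty_allowed_raises(self, toy2_model):
        with pytest.raises(ValueError):
            conditional_distribution(toy2_model, np.array([1, 2]), 0, [], 1.0)

    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_probability_vector(self, seed):
        model = make_random_model(seed % 17, L=5, q=4)
        rng = np.random.default_rng(seed)
        seq = rng.integers(4, size=5)
        allowed = sorted(rng.choice(4, size=int(rng.integers(1, 5)),
                                    replace=False))
        p = conditional_distribution(model, seq, int(rng.integers(5)),
                                     allowed, beta=float(rng.random() * 5))
        assert (p >= 0).all()
        assert p.sum() == pytest.approx(1.0, abs=1e-12)


class TestZeroSumGauge:
    def test_idempotent(self):
        model = zero_sum_gauge(make_random_model(3))
        again = zero_sum_gauge(model)
        assert np.allclose(model.h, again.h, atol=1e-12)
        assert np.allclose(model.J, again.J, atol=1e-12)

    def test_row_and_column_sums_vanish(self):
        g = zero_sum_gauge(make_random_model(4))
        assert np.abs(g.h.sum(axis=1)).max() < 1e-10
        assert np.abs(g.J.sum(axis=2)).max() < 1e-10
        assert np.abs(g.J.sum(axis=3)).max() < 1e-10

    def test_delta_energy_invariant(self):
        model = make_random_model(5, L=6, q=4)
        gauged = zero_sum_gauge(model)
        rng = np.random.default_rng(9)
        for _ in range(100):
            seq = rng.integers(4, size=6)
            site, b = int(rng.integers(6)), int(rng.integers(4))
            assert delta_energy(model, seq, site, b) == pytest.approx(
                delta_energy(gauged, seq, site, b), abs=1e-10)


class TestProfileFromMsa:
    def test_single_sequence_formula(self):
        profile = profile_from_msa(["ACD"], pseudocount=0.5)
        f = np.exp(profile.h)
        expected_hit = 0.5 + 0.5 / 21
        assert f[0, PROTEIN.index("A")] == pytest.approx(expected_hit)
        assert f[0, PROTEIN.index("C")] == pytest.approx(0.5 / 21)

    def test_full_pseudocount_is_uniform(self):
        profile = profile_from_msa(["ACD", "WYF"], pseudocount=1.0)
        assert np.allclose(profile.h, profile.h[0, 0])

    def test_recovers_fields_from_equilibrium_sample(self):
        # log-frequency fields equal the true fields up to a per-site
        # normalization constant, so compare after row-centering
        from scipy.stats import spearmanr
        rng = np.random.default_rng(12)
        L, q = 20, 4
        alphabet = Alphabet("ABCD", gap=None)
        h = rng.normal(size=(L, q))
        model = ProfileModel(h, alphabet)
        msa = gibbs_sample(model, 10_000, burn_in=5, thinning=1, seed=3)
        prof = profile_from_msa(msa, pseudocount=0.001, alphabet=alphabet)
        h_c = h - h.mean(axis=1, keepdims=True)
        g_c = prof.h - prof.h.mean(axis=1, keepdims=True)
        rho = spearmanr(h_c.ravel(), g_c.ravel()).statistic
        assert rho > 0.9


class TestParamsIO:
    def test_round_trip_bitwise(self, tmp_path):
        model = make_random_model(11, L=4, q=3)
        path = tmp_path / "m.params"
        write_params(path, model)
        back = read_params(path, alphabet=model.alphabet)
        assert (back.h == model.h).all()
        assert (back.J == model.J).all()

    def test_fields_only_file(self, tmp_path):
        path = tmp_path / "h.params"
        path.write_text("# evoscape potts params L=2 q=21\nh 0 3 1.25\n")
        model = read_params(path)
        assert model.h[0, 3] == 1.25
        assert not model.J.any()

    def test_single_coupling_symmetrized(self, tmp_path):
        path = tmp_path / "j.params"
        path.write_text("# evoscape potts params L=3 q=21\nJ 0 2 1 4 0.75\n")
        model = read_params(path)
        assert model.J[0, 2, 1, 4] == 0.75
        assert model.J[2, 0, 4, 1] == 0.75

    def test_malformed_line_raises(self, tmp_path):
        path = tmp_path / "bad.params"
        path.write_text("h 0 zero 1.0\n")
        with pytest.raises(ValueError, match="malformed"):
            read_params(path)

    def test_out_of_range_index_raises(self, tmp_path):
        path = tmp_path / "oob.params"
        path.write_text("# evoscape potts params L=2 q=21\nh 5 0 1.0\n")
        with pytest.raises(ValueError, match="out of range"):
            read_params(path)
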