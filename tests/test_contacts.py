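import numpy as np
import pandas as pd
import pytest

from evoscape.contactmap import ContactMap, contact_map_from_distances
from evoscape.contacts import (ScoreMatrix, apc_correction, gauss_dca_scores,
                               parameter_scan, ppv, ppv_null, ranked_pairs,
                               sequence_weights)


class TestContactMap:
    def test_strict_cutoff_and_separation(self):
        tab = pd.DataFrame({"i": [0, 0, 0], "j": [5, 6, 4],
                            "distance": [7.9, 8.0, 3.0]})
        cmap = contact_map_from_distances(tab, L=10)
        assert (0, 5) in cmap          # 7.9 < 8
        assert (0, 6) not in cmap      # 8.0 excluded (strict)
        assert (0, 4) not in cmap      # |i-j| = 4 < 5
        assert len(cmap) == 1

    def test_empty_table(self):
        cmap = contact_map_from_distances(pd.DataFrame(columns=["i", "j", "distance"]),
                                          L=10)
        assert len(cmap) == 0

    def test_negative_distance_raises(self):
        tab = pd.DataFrame({"i": [0], "j": [6], "distance": [-1.0]})
        with pytest.raises(ValueError):
            contact_map_from_distances(tab, L=10)

    def test_invariants(self):
        with pytest.raises(ValueError):
            ContactMap(L=10, contacts={(2, 2)})
        with pytest.raises(ValueError):
            ContactMap(L=10, contacts={(2, 4)})  # separation < 5
        cmap = ContactMap(L=10, contacts={(7, 1)})  # normalized to (1, 7)
        assert (1, 7) in cmap and (7, 1) in cmap


class TestSequenceWeights:
    def test_distinct_sequences_unit_weight(self):
        rng = np.random.default_rng(0)
        msa = rng.integers(21, size=(10, 40))
        w = sequence_weights(msa, 0.8)
        assert np.allclose(w, 1.0)

    def test_duplicates_downweighted(self):
        msa = np.vstack([np.zeros((4, 8)), np.ones((1, 8))]).astype(int)
        w = sequence_weights(msa, 1.0)
        assert np.allclose(w[:4], 0.25)
        assert w[4] == 1.0

    def test_off_mode(self):
        msa = np.zeros((5, 4), dtype=int)
        assert np.allclose(sequence_weights(msa, "off"), 1.0)

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(1)
        msa = rng.integers(3, size=(12, 10))
        thr = 0.7
        w = sequence_weights(msa, thr)
        for s in range(12):
            n = sum((msa[s] == msa[t]).mean() >= thr for t in range(12))
            assert w[s] == pytest.approx(1.0 / n)


class TestGaussDca:
    def test_covarying_pair_ranks_first(self):
        rng = np.random.default_rng(2)
        M, L = 400, 12
        msa = rng.integers(4, size=(M, L))
        msa[:, 8] = msa[:, 1]  # perfectly covarying, separation 7
        scores = gauss_dca_scores(msa, pseudocount=0.3, q=4)
        pairs = ranked_pairs(scores, min_separation=5)
        assert pairs[0] == (1, 8)

    def test_permutation_invariance(self):
        rng = np.random.default_rng(3)
        msa = rng.integers(4, size=(60, 8))
        s1 = gauss_dca_scores(msa, pseudocount=0.5, q=4)
        s2 = gauss_dca_scores(msa[rng.permutation(60)], pseudocount=0.5, q=4)
        assert np.allclose(s1.values, s2.values, atol=1e-10)

    def test_null_msa_no_dominant_pair(self):
        rng = np.random.default_rng(4)
        msa = rng.integers(4, size=(3000, 10))
        scores = gauss_dca_scores(msa, pseudocount=0.5, q=4, apc=False)
        off = scores.values[np.triu_indices(10, k=1)]
        assert off.max() < 5 * np.median(off)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            gauss_dca_scores(np.zeros((1, 5), dtype=int))
        with pytest.raises(ValueError):
            gauss_dca_scores(np.zeros((5, 5), dtype=int), pseudocount=1.5)


class TestApc:
    def test_constant_offdiagonal_zeroed(self):
        S = np.full((6, 6), 0.7)
        np.fill_diagonal(S, 0.0)
        out = apc_correction(ScoreMatrix(S)).values
        assert np.allclose(out, 0.0, atol=1e-12)

    def test_symmetry_preserved(self):
        rng = np.random.default_rng(5)
        A = rng.random((8, 8))
        S = 0.5 * (A + A.T)
        np.fill_diagonal(S, 0.0)
        out = apc_correction(ScoreMatrix(S)).values
        assert np.allclose(out, out.T)

    def test_matches_three_loop_oracle(self):
        rng = np.random.default_rng(6)
        for _ in range(10):
            A = rng.random((6, 6))
            S = 0.5 * (A + A.T)
            np.fill_diagonal(S, 0.0)
            out = apc_correction(ScoreMatrix(S)).values
            L = 6
            row = [sum(S[i, j] for j in range(L) if j != i) / (L - 1)
                   for i in range(L)]
            tot = sum(S[i, j] for i in range(L) for j in range(L) if i != j) \
                / (L * (L - 1))
            for i in range(L):
                for j in range(L):
                    if i != j:
                        assert out[i, j] == pytest.approx(
                            S[i, j] - row[i] * row[j] / tot, abs=1e-12)

    def test_all_zero_unchanged(self):
        out = apc_correction(ScoreMatrix(np.zeros((4, 4))))
        assert not out.values.any()


class TestPpv:
    def _map(self):
        return ContactMap(L=20, contacts={(0, 10), (1, 8), (2, 12), (3, 15)})

    def test_perfect_ranking(self):
        cmap = self._map()
        S = np.zeros((20, 20))
        for (i, j) in cmap.contacts:
            S[i, j] = S[j, i] = 1.0
        assert ppv(ScoreMatrix(S), cmap, 4) == 1.0

    def test_no_contacts_gives_zero(self):
        S = np.random.default_rng(7).random((20, 20))
        S = 0.5 * (S + S.T)
        np.fill_diagonal(S, 0)
        assert ppv(ScoreMatrix(S), ContactMap(L=20, contacts=set()), 10) == 0.0

    def test_too_many_predictions_raises(self):
        with pytest.raises(ValueError):
            ppv(ScoreMatrix(np.zeros((8, 8))), ContactMap(L=8), 100)

    def test_random_ranking_matches_density(self):
        cmap = ContactMap(L=30, contacts={(i, i + 6) for i in range(0, 24, 2)})
        mean, sd = ppv_null(cmap, 15, n_permutations=1000, seed=8)
        assert abs(mean - cmap.density) < 3 * sd / np.sqrt(1000)


class TestParameterScan:
    def test_single_cell_deterministic(self, planted):
        model, cmap, wt = planted
        kwargs = dict(T_values=[1.0], snapshot_steps=[40], library_sizes=[80],
                      n_replicates=1, contact_map=cmap, seed=5,
                      n_predictions=10)
        a = parameter_scan(model, wt, **kwargs)
        b = parameter_scan(model, wt, **kwargs)
        assert a[["mean_ppv", "mean_hamming"]].equals(
            b[["mean_ppv", "mean_hamming"]])

    def test_grid_shape_and_columns(self, planted):
        model, cmap, wt = planted
        grid = parameter_scan(model, wt, [1.0], [10, 40], [50, 100], 2, cmap,
                              seed=6, n_predictions=10)
        assert len(grid) == 4
        assert {"T", "steps", "M", "mean_ppv", "sd_ppv",
                "mean_hamming"} <= set(grid.columns)
        reps = grid.attrs["replicates"]
        assert len(reps) == 8
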