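import numpy as np
import pytest

import ecolag as e
from oracles import global_moran_brute, local_moran_brute


class TestGlobalCrossMoran:
    def test_reduces_to_univariate_moran(self, row_w, rng):
        """x_lagged = y collapses the statistic to the classical Moran's I
        of y (computed here from its defining ratio as the oracle)."""
        y = rng.standard_normal(16)
        I = e.global_cross_moran(y, y, row_w)
        W = row_w.to_dense()
        d = y - y.mean()
        I_uni = (16 / W.sum()) * (d @ W @ d) / (d @ d)
        assert I == pytest.approx(I_uni, abs=1e-12)

    def test_brute_force_oracle(self, row_w, rng):
        for _ in range(20):
            y, x = rng.standard_normal((2, 16))
            expect = global_moran_brute(list(y), list(x), row_w.ids,
                                        row_w.neighbors, row_w.weights)
            assert e.global_cross_moran(y, x, row_w) == pytest.approx(
                expect, abs=1e-12)

    def test_permutation_null_mean_near_zero(self, row_w, rng):
        y = rng.standard_normal(16)
        x = rng.standard_normal(16)
        zx = (x - x.mean()) / x.std()
        a = row_w.to_dense().T @ ((y - y.mean()) / y.std())
        perms = np.array([rng.permutation(16) for _ in range(2000)])
        I_perm = zx[perms] @ a / row_w.s0()
        se = I_perm.std() / np.sqrt(2000)
        assert abs(I_perm.mean()) < 3 * se + 1e-3

    def test_constant_variable_errors(self, row_w):
        with pytest.raises(ValueError, match="constant"):
            e.global_cross_moran(np.ones(16), np.arange(16.0), row_w)


class TestLocalCrossMoran:
    def test_mean_local_equals_global(self, row_w, rng):
        for _ in range(10):
            y, x = rng.standard_normal((2, 16))
            local = e.local_cross_moran(y, x, row_w)
            assert local.mean() == pytest.approx(
                e.global_cross_moran(y, x, row_w), abs=1e-10)

    def test_brute_force_oracle(self, row_w, rng):
        y, x = rng.standard_normal((2, 16))
        expect = local_moran_brute(list(y), list(x), row_w.ids,
                                   row_w.neighbors, row_w.weights)
        assert np.allclose(e.local_cross_moran(y, x, row_w), expect,
                           atol=1e-12)

    def test_unit_value_is_zy_times_neighbour_lag(self, row_w):
        # hand-check one unit: neighbours of r0-0 are r0-1, r1-0, r1-1
        y = np.arange(16.0)
        x = np.zeros(16)
        ids = row_w.ids
        x[ids.index("r0-1")] = 1.0
        x[ids.index("r1-0")] = -1.0
        x[ids.index("r1-1")] = 0.0
        zx_ = (x - x.mean()) / x.std()
        lag0 = sum(w * zx_[ids.index(j)] for j, w in
                   zip(row_w.neighbors["r0-0"], row_w.weights["r0-0"]))
        local = e.local_cross_moran(y, x, row_w)
        zy = (y - y.mean()) / y.std()
        assert local[0] == pytest.approx(zy[0] * lag0, abs=1e-12)


class TestMoranScatter:
    def test_slope_equals_global_I(self, row_w, rng):
        for _ in range(10):
            y, x = rng.standard_normal((2, 16))
            _, slope = e.moran_scatter(y, x, row_w)
            assert slope == pytest.approx(
                e.global_cross_moran(y, x, row_w), abs=1e-10)

    def test_scatter_values_are_lag_and_zy(self, row_w, rng):
        y, x = rng.standard_normal((2, 16))
        scatter, _ = e.moran_scatter(y, x, row_w)
        zy = (y - y.mean()) / y.std()
        assert np.allclose(scatter[:, 1], zy, atol=1e-12)


class TestPermutationInference:
    def test_deterministic_given_seed(self, row_w, rng):
        y, x = rng.standard_normal((2, 16))
        a = e.permutation_inference(y, x, row_w, n_perm=199, seed=5)
        b = e.permutation_inference(y, x, row_w, n_perm=199, seed=5)
        assert a["p_value"] == b["p_value"]
        assert np.array_equal(a["local_p"], b["local_p"])

    def test_minimum_permutations_enforced(self, row_w, rng):
        y, x = rng.standard_normal((2, 16))
        with pytest.raises(ValueError):
            e.permutation_inference(y, x, row_w, n_perm=50)

    def test_power_against_coupled_fields(self):
        """y spatially coupled to x (shared SAR field, rho=0.9, tight
        noise): the global permutation test should reject in >80% of
        replicates.  A 6x6 lattice gives the test room to see the
        structure."""
        w = e.row_standardize(e.queen_contiguity(
            e.generate_regions(e.SyntheticConfig(n_side=6))))
        rng = np.random.default_rng(9)
        n = w.n
        A = np.linalg.inv(np.eye(n) - 0.9 * w.to_dense())
        hits = 0
        for _ in range(50):
            x = A @ rng.standard_normal(n)
            y = 2 * (x - x.mean()) / x.std() + 0.1 * rng.standard_normal(n)
            p = e.permutation_inference(
                y, x, w, n_perm=199,
                seed=int(rng.integers(2 ** 31)), compute_local=False)["p_value"]
            hits += p <= 0.05
        assert hits / 50 > 0.8

    def test_global_type_i_calibration(self, row_w):
        """Independent y, x: rejection rate at alpha=0.05 stays within
        0.05 +/- 0.015 (2000 replicates x 199 permutations)."""
        rng = np.random.default_rng(31)
        W = row_w.to_dense()
        s0 = W.sum()
        rejections = 0
        n_rep = 2000
        for _ in range(n_rep):
            y, x = rng.standard_normal((2, 16))
            zy = (y - y.mean()) / y.std()
            zx = (x - x.mean()) / x.std()
            I_obs = zy @ W @ zx / s0
            a = W.T @ zy
            perms = np.array([rng.permutation(16) for _ in range(199)])
            I_perm = zx[perms] @ a / s0
            p = ((np.abs(I_perm) >= abs(I_obs) - 1e-14).sum() + 1) / 200
            rejections += p <= 0.05
        assert rejections / n_rep == pytest.approx(0.05, abs=0.015)


class TestLisaClassify:
    def test_quadrant_rule(self, row_w, rng):
        y, x = rng.standard_normal((2, 16))
        zy = (y - y.mean()) / y.std()
        zx = (x - x.mean()) / x.std()
        lag = row_w.to_dense() @ zx
        labels = e.lisa_classify(y, x, row_w, np.zeros(16), alpha=0.05)
        for i, lab in enumerate(labels):
            if zy[i] >= 0:
                assert lab == ("high-high" if lag[i] >= 0 else "high-low")
            else:
                assert lab == ("low-low" if lag[i] < 0 else "low-high")

    def test_all_not_significant_when_p_large(self, row_w, rng):
        y, x = rng.standard_normal((2, 16))
        labels = e.lisa_classify(y, x, row_w, np.ones(16), alpha=0.05)
        assert set(labels) == {"not_significant"}

    def test_planted_low_low_cluster(self):
        """A low-y region whose neighbours carry low x in an otherwise
        high field must label low-low on a 5x5 grid."""
        regions = e.generate_regions(e.SyntheticConfig(n_side=5))
        w = e.row_standardize(e.queen_contiguity(regions))
        ids = w.ids
        rng = np.random.default_rng(4)
        y = 10 + 0.1 * rng.standard_normal(25)
        x = 10 + 0.1 * rng.standard_normal(25)
        center = ids.index("r2-2")
        y[center] = 0.0
        for j in w.neighbors["r2-2"]:
            x[ids.index(j)] = 0.0
        res = e.cross_moran(y, x, w, n_perm=999, seed=0)
        assert res.cluster[center] == "low-low"


class TestPearsonLag:
    def panel(self, vals, var="X"):
        return e.PanelTable(var, [f"r{i}" for i in range(len(vals))],
                            [2010, 2015, 2020],
                            np.column_stack([vals, vals, vals]))

    def test_identical_series_r_one(self, rng):
        v = rng.standard_normal(10)
        le = self.panel(v, "LE")
        rows = e.pearson_lag_matrix({"X": self.panel(v)}, le,
                                    [e.LagPair("LE", 2015, "X", 2010)])
        assert rows[0]["pearson_r"] == pytest.approx(1.0)
        assert rows[0]["m"] == 5

    def test_negated_series_r_minus_one(self, rng):
        v = rng.standard_normal(10)
        rows = e.pearson_lag_matrix({"X": self.panel(-v)}, self.panel(v, "LE"),
                                    [e.LagPair("LE", 2020, "X", 2020)])
        assert rows[0]["pearson_r"] == pytest.approx(-1.0)

    def test_lagged_r_beats_contemporaneous_on_synthetic(self):
        """Generator ground truth: with a strong one-step effect, r(LE(t),
        CEI(t-1)) exceeds r(LE(t), CEI(t)) in most replicates."""
        cfg0 = e.SyntheticConfig()
        w = e.row_standardize(e.queen_contiguity(e.generate_regions(cfg0)))
        wins = 0
        n_rep = 60
        for s in range(n_rep):
            c = e.SyntheticConfig(seed=s, beta_le=2.0, noise_sd_le=0.1,
                                  lag_m=1)
            study = e.generate_study(c)
            le, cei = study["le"], study["cei"]
            pairs = [e.LagPair("LE", 2020, "CEI", 2015),
                     e.LagPair("LE", 2020, "CEI", 2020)]
            rows = e.pearson_lag_matrix({"CEI": cei}, le, pairs)
            wins += rows[0]["pearson_r"] > rows[1]["pearson_r"]
        assert wins / n_rep > 0.5

    def test_analytic_r_for_standardized_predictor(self):
        # r = beta / sqrt(beta^2 + sigma^2) for LE = 73 + beta*z + noise
        cfg = e.SyntheticConfig(seed=1, beta_le=2.0, noise_sd_le=0.1)
        study = e.generate_study(cfg)
        rows = e.pearson_lag_matrix({"CEI": study["cei"]}, study["le"],
                                    [e.LagPair("LE", 2020, "CEI", 2015)])
        assert rows[0]["pearson_r"] > 0.9

    def test_too_few_pairs_errors(self):
        p = self.panel(np.array([1.0, 2.0]))
        with pytest.raises(ValueError, match="fewer than 3"):
            e.pearson_lag_matrix({"X": p}, self.panel(np.array([1.0, 2.0]), "LE"),
                                 [e.LagPair("LE", 2015, "X", 2010)])

    def test_negative_lag_rejected(self):
        with pytest.raises(ValueError, match="negative lag"):
            e.LagPair("LE", 2010, "X", 2015)
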