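"""SVD activity levels, permutation null and GEV calibration."""

import math

import numpy as np
import pytest
from scipy import stats

from metsetrank import synthetic
from metsetrank.benchmark import run_methods
from metsetrank.mplage import (
    GevParams,
    activity_levels,
    calibrated_p_value,
    empirical_p_value,
    fit_gev,
    permutation_null,
    run_mplage,
    set_t_statistic,
    welch_t,
)
from metsetrank.set_sources import map_database

DESIGN = {"case": ["c1", "c2", "c3", "c4"], "control": ["k1", "k2", "k3", "k4"]}
SAMPLES = DESIGN["case"] + DESIGN["control"]
COMPARISON = ("case", "control")


class TestActivityLevels:
    def test_rank_one_closed_form(self):
        X = np.tile([1.0, 2.0, 3.0, 4.0], (5, 1))
        al = activity_levels(X)
        expect = np.array([1, 2, 3, 4]) / math.sqrt(30)
        np.testing.assert_allclose(al, expect, atol=1e-12)

    def test_single_feature_is_scaled_row(self):
        row = np.array([[3.0, -4.0, 0.0, 12.0]])
        al = activity_levels(row)
        np.testing.assert_allclose(al, row[0] / 13.0, atol=1e-12)

    def test_matches_full_svd_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            X = rng.standard_normal((6, 8))
            al = activity_levels(X)
            # independent oracle: full SVD via eigen-decomposition of X^T X
            w, v = np.linalg.eigh(X.T @ X)
            lead = v[:, np.argmax(w)]
            lead = lead if lead[np.argmax(np.abs(lead))] > 0 else -lead
            np.testing.assert_allclose(al, lead, atol=1e-10)
            assert np.linalg.norm(al) == pytest.approx(1.0)

    def test_sign_convention(self):
        al = activity_levels(np.array([[-5.0, 1.0, 1.0, 1.0]]))
        assert al[np.argmax(np.abs(al))] > 0


class TestTStatistic:
    def test_identical_groups_zero(self):
        al = np.ones(8)
        assert set_t_statistic(al, SAMPLES, DESIGN, COMPARISON) == 0.0

    def test_antisymmetric_under_group_swap(self):
        rng = np.random.default_rng(3)
        al = rng.standard_normal(8)
        t_fwd = set_t_statistic(al, SAMPLES, DESIGN, COMPARISON)
        t_rev = set_t_statistic(al, SAMPLES, DESIGN, ("control", "case"))
        assert t_fwd == pytest.approx(-t_rev)

    def test_matches_scipy_welch(self):
        x = np.array([2.1, 1.9, 2.0, 2.0])
        y = np.array([1.0, 1.1, 0.9, 1.0])
        expected = stats.ttest_ind(x, y, equal_var=False).statistic
        assert welch_t(x, y) == pytest.approx(expected, rel=1e-12)
        al = np.concatenate([x, y])
        t = set_t_statistic(al, SAMPLES, DESIGN, COMPARISON)
        assert t == pytest.approx(expected, rel=1e-12)

    def test_zero_variance_sentinel(self):
        t = welch_t(np.array([2.0, 2.0]), np.array([1.0, 1.0]))
        assert t == 1e6 and np.isfinite(t)


class TestPermutationNull:
    def _al_matrix(self, n_sets=12, seed=0):
        return np.random.default_rng(seed).standard_normal((n_sets, 8))

    def test_deterministic_given_seed(self):
        A = self._al_matrix()
        with pytest.warns(RuntimeWarning, match="distinct labelings"):
            n1 = permutation_null(A, SAMPLES, DESIGN, COMPARISON, 1000, seed=5)
        with pytest.warns(RuntimeWarning):
            n2 = permutation_null(A, SAMPLES, DESIGN, COMPARISON, 1000, seed=5)
        np.testing.assert_array_equal(n1.max_t, n2.max_t)
        np.testing.assert_array_equal(n1.min_t, n2.min_t)

    def test_min_le_max_invariant(self):
        A = self._al_matrix(seed=2)
        null = permutation_null(A, SAMPLES, DESIGN, COMPARISON, 500, seed=1)
        assert (null.min_t <= null.max_t).all()

    def test_null_data_gives_central_observed_t(self):
        # no group effect: observed t should sit inside the null's bulk
        inside = 0
        for rep in range(20):
            A = self._al_matrix(n_sets=1, seed=100 + rep)
            t_obs = set_t_statistic(A[0], SAMPLES, DESIGN, COMPARISON)
            null = permutation_null(A, SAMPLES, DESIGN, COMPARISON, 400,
                                    seed=rep)
            p = empirical_p_value(t_obs, null)
            inside += p > 0.05
        assert inside >= 18  # >=90% of replicates


class TestGev:
    def test_gumbel_parameter_recovery(self):
        draws = stats.gumbel_r.rvs(
            loc=0.0, scale=1.0, size=10_000,
            random_state=np.random.default_rng(11),
        )
        fit = fit_gev(draws)
        assert fit.loc == pytest.approx(0.0, abs=0.05)
        assert fit.scale == pytest.approx(1.0, abs=0.05)
        assert fit.shape == pytest.approx(0.0, abs=0.05)

    def test_gumbel_cdf_at_location(self):
        g = GevParams(loc=2.0, scale=1.5, shape=0.0)
        assert g.cdf(2.0) == pytest.approx(math.exp(-1), rel=1e-12)

    def test_mle_beats_moment_start(self):
        rng = np.random.default_rng(4)
        draws = stats.genextreme.rvs(-0.1, loc=1, scale=2, size=2000,
                                     random_state=rng)
        fit = fit_gev(draws)
        # moment-based Gumbel start: scale = sd*sqrt(6)/pi, loc = mean - g*scale
        scale0 = draws.std() * math.sqrt(6) / math.pi
        loc0 = draws.mean() - 0.5772 * scale0
        ll0 = stats.genextreme.logpdf(draws, 0.0, loc=loc0, scale=scale0).sum()
        assert fit.loglik >= ll0

    def test_too_few_extremes_rejected(self):
        with pytest.raises(ValueError):
            fit_gev(np.ones(50))


class TestCalibratedP:
    def _fits(self):
        rng = np.random.default_rng(8)
        mx = stats.gumbel_r.rvs(loc=2, scale=0.5, size=5000, random_state=rng)
        mn = -stats.gumbel_r.rvs(loc=2, scale=0.5, size=5000, random_state=rng)
        return fit_gev(mx), fit_gev(-mn)

    def test_far_right_tail(self):
        gmax, gmin = self._fits()
        t = 20.0
        p = calibrated_p_value(t, gmax, gmin)
        assert p == pytest.approx(2 * float(gmax.sf(t)), rel=1e-9, abs=1e-300)
        assert p < 1e-6

    def test_central_value_near_one(self):
        gmax, gmin = self._fits()
        assert calibrated_p_value(0.0, gmax, gmin) > 0.5

    def test_floor_flag(self):
        gmax, gmin = self._fits()
        p = calibrated_p_value(50.0, gmax, gmin, n_perm=999,
                               floor_at_resolution=True)
        assert p == pytest.approx(1 / 1000)

    def test_no_floor_by_default(self):
        gmax, gmin = self._fits()
        p = calibrated_p_value(50.0, gmax, gmin)
        assert 0 < p < 1e-4  # analytic sub-resolution tail


@pytest.fixture(scope="module")
def ds():
    return synthetic.generate_base(123)


class TestRunMplage:
    def test_column_order_invariance(self, ds):
        from metsetrank.data_model import IntensityMatrix

        res1 = run_methods(ds, ["mplage"], n_perm_mplage=300, seed=9)["mplage"]
        cols = list(ds.matrix.values.columns)[::-1]
        shuffled = synthetic.SyntheticDataset(
            matrix=IntensityMatrix(ds.matrix.values[cols], ds.matrix.design),
            annotations=ds.annotations,
            database=ds.database,
            truth=ds.truth,
            comparison=ds.comparison,
            seed=ds.seed,
        )
        res2 = run_methods(shuffled, ["mplage"], n_perm_mplage=300, seed=9)["mplage"]
        for sid, p in res1.items():
            assert res2[sid] == pytest.approx(p, rel=1e-9, nan_ok=True)

    def test_al_sign_invariance(self):
        # negating the AL vector must not change the p-value
        gmax = GevParams(loc=3, scale=0.5, shape=0.0)
        gmin = GevParams(loc=3, scale=0.5, shape=0.0)
        for t in (-4.2, -1.0, 0.3, 5.5):
            p_pos = calibrated_p_value(t, gmax, gmin)
            p_neg = calibrated_p_value(-t, gmax, gmin)
            assert p_pos == pytest.approx(p_neg, rel=1e-12)

    def test_ranked_output_schema_and_order(self, ds):
        mapping = map_database(ds.database, ds.annotations, ds.matrix)
        table = run_mplage(ds.matrix, ds.database, mapping, ds.comparison,
                           n_perm=300, seed=4)
        assert list(table.columns) == [
            "set_id", "name", "n_features", "coverage", "t_statistic",
            "p_value", "rank", "flags",
        ]
        ps = table["p_value"].dropna().to_numpy()
        assert (np.diff(ps) >= 0).all()
        assert table["rank"].tolist() == list(range(1, len(table) + 1))

    def test_planted_large_sets_outrank_background(self, ds):
        res = run_methods(ds, ["mplage"], n_perm_mplage=1000, seed=2)["mplage"]
        worst_planted = max(res[s] for s in ("Twenty", "Forty", "Eighty"))
        bg = [p for s, p in res.items() if s.startswith("BG")]
        assert worst_planted < np.quantile(bg, 0.05)

    def test_no_scoreable_sets_is_error(self, ds):
        mapping = {s.set_id: [] for s in ds.database}
        with pytest.raises(ValueError, match="no scoreable sets"):
            run_mplage(ds.matrix, ds.database, mapping, ds.comparison,
                       n_perm=300, seed=0)

    def test_per_set_scope_null_uniformity(self):
        # with per-set permutation scope, null p-values are not conservative
        ds = synthetic.generate_base(9, effect_size=0.0)
        mapping = map_database(ds.database, ds.annotations, ds.matrix)
        table = run_mplage(ds.matrix, ds.database, mapping, ds.comparison,
                           n_perm=1000, seed=3, scope="per_set")
        ps = table["p_value"].dropna().to_numpy()
        assert stats.kstest(ps, "uniform").statistic < 0.15
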