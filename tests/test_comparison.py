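"""ORA and GSEA reference implementations."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from metsetrank import synthetic
from metsetrank.benchmark import run_methods
from metsetrank.comparison import (
    enrichment_score,
    feature_significance,
    gsea,
    ora,
)
from metsetrank.data_model import IntensityMatrix
from metsetrank.set_sources import map_database

DESIGN = {"case": ["c1", "c2", "c3", "c4"], "control": ["k1", "k2", "k3", "k4"]}
COMPARISON = ("case", "control")


def _matrix(vals, features=None):
    features = features or [f"f{i}" for i in range(len(vals))]
    return IntensityMatrix(
        pd.DataFrame(
            vals, index=features, columns=DESIGN["case"] + DESIGN["control"]
        ),
        DESIGN,
    )


class TestFeatureSignificance:
    def test_flat_feature_not_de(self):
        m = _matrix([[5.0] * 8])
        sig = feature_significance(m, COMPARISON)
        assert not sig["de"].iloc[0] and sig["p"].iloc[0] == 1.0

    def test_extreme_separation_is_de(self):
        m = _matrix([[10.0, 10.1, 9.9, 10.0, 0.0, 0.1, -0.1, 0.0]])
        sig = feature_significance(m, COMPARISON)
        assert sig["de"].iloc[0]

    def test_matches_scipy_oracle(self):
        rng = np.random.default_rng(19)
        vals = rng.standard_normal((100, 8))
        m = _matrix(vals.tolist())
        sig = feature_significance(m, COMPARISON, alpha_feature=0.1)
        t, p = stats.ttest_ind(vals[:, :4], vals[:, 4:], axis=1,
                               equal_var=False)
        np.testing.assert_allclose(sig["p"], p, rtol=1e-12)
        np.testing.assert_array_equal(sig["de"], p < 0.1)


def brute_force_hypergeom_upper(N, K, n, k):
    """Exhaustive enumeration of P(X >= k), X ~ Hypergeom(N, K, n)."""
    total = math.comb(N, n)
    return sum(
        math.comb(K, j) * math.comb(N - K, n - j)
        for j in range(k, min(K, n) + 1)
        if n - j <= N - K
    ) / total


class TestOra:
    @staticmethod
    def _setup(de_flags, set_members):
        """Build a matrix whose DE features are exactly `de_flags`."""
        rng = np.random.default_rng(5)
        rows = []
        for de in de_flags:
            base = rng.normal(0, 0.05, 8)
            if de:
                base[:4] += 50.0
            rows.append(base + 100.0)
        m = _matrix(rows)
        from metsetrank.set_sources import MetaboliteSet, database_from_sets

        sets = [
            MetaboliteSet(sid, sid, tuple(members), "feature")
            for sid, members in set_members.items()
        ]
        db = database_from_sets(sets)
        mapping = map_database(db, None, m)
        return m, db, mapping

    def test_matches_enumeration_oracle(self):
        # N=20 background, K=5 in set, n=8 DE, k=4 DE in set
        de = [True] * 4 + [False] + [True] * 4 + [False] * 11
        members = {
            "S": [f"f{i}" for i in range(5)],
            "rest": [f"f{i}" for i in range(5, 20)],
        }
        m, db, mapping = self._setup(de, members)
        res = ora(m, db, mapping, COMPARISON)
        row = res[res["set_id"] == "S"].iloc[0]
        assert (row["n_background"], row["n_features"],
                row["n_de_background"], row["k_de"]) == (20, 5, 8, 4)
        assert row["p_value"] == pytest.approx(
            brute_force_hypergeom_upper(20, 5, 8, 4), rel=1e-12
        )

    def test_k_zero_gives_p_one(self):
        de = [False] * 5 + [True] * 5
        members = {"S": [f"f{i}" for i in range(5)],
                   "rest": [f"f{i}" for i in range(5, 10)]}
        m, db, mapping = self._setup(de, members)
        res = ora(m, db, mapping, COMPARISON)
        assert res[res["set_id"] == "S"]["p_value"].iloc[0] == pytest.approx(1.0)

    def test_monotone_in_k(self):
        # p strictly decreases as k rises at fixed (N, K, n)
        ps = [brute_force_hypergeom_upper(20, 5, 8, k) for k in range(6)]
        assert all(a > b for a, b in zip(ps, ps[1:]))
        # and the scipy-backed implementation agrees everywhere
        for k in range(6):
            assert stats.hypergeom.sf(k - 1, 20, 5, 8) == pytest.approx(
                ps[k], rel=1e-12
            )

    def test_fully_de_set_is_smallest_p(self):
        de = [True] * 5 + [False] * 10 + [True] * 0
        members = {
            "hot": [f"f{i}" for i in range(5)],
            "cold": [f"f{i}" for i in range(5, 10)],
            "mixed": [f"f{i}" for i in range(3, 8)],
        }
        m, db, mapping = self._setup(de, members)
        res = ora(m, db, mapping, COMPARISON).set_index("set_id")
        assert res.loc["hot", "p_value"] == res["p_value"].min()

    def test_column_order_invariance(self):
        de = [True] * 3 + [False] * 7
        members = {"S": [f"f{i}" for i in range(5)],
                   "rest": [f"f{i}" for i in range(5, 10)]}
        m, db, mapping = self._setup(de, members)
        p1 = ora(m, db, mapping, COMPARISON).set_index("set_id")["p_value"]
        cols = list(m.values.columns)[::-1]
        m2 = IntensityMatrix(m.values[cols], m.design)
        p2 = ora(m2, db, mapping, COMPARISON).set_index("set_id")["p_value"]
        pd.testing.assert_series_equal(p1, p2)


class TestEnrichmentScore:
    def hand_stepped_es(self, metric, hits, weight=1.0):
        """Literal running-sum oracle, O(N)."""
        order = np.argsort(-metric, kind="stable")
        nr = sum(abs(metric[i]) ** weight for i in hits)
        miss = len(metric) - len(hits)
        running, best = 0.0, 0.0
        for idx in order:
            if idx in hits:
                running += abs(metric[idx]) ** weight / nr
            else:
                running -= 1.0 / miss
            if abs(running) > abs(best):
                best = running
        return best

    def test_matches_hand_stepped_oracle(self):
        rng = np.random.default_rng(23)
        metric = rng.standard_normal(10)
        for hits in itertools.combinations(range(10), 3):
            es = enrichment_score(metric, np.array(hits))
            assert es == pytest.approx(
                self.hand_stepped_es(metric, set(hits)), abs=1e-12
            )
            assert -1.0 <= es <= 1.0

    def test_top_ranked_set_has_maximal_es(self):
        metric = np.linspace(3, -3, 20)
        top = enrichment_score(metric, np.arange(4))
        others = [
            enrichment_score(metric, np.array(c))
            for c in itertools.combinations(range(20), 4)
        ]
        assert top == pytest.approx(max(others))
        assert top > 0

    def test_interspersed_set_near_zero(self):
        # with unit steps (weight 0) an evenly spread set has no net drift
        metric = np.linspace(1, -1, 21)
        es = enrichment_score(metric, np.array([0, 5, 10, 15, 20]), weight=0.0)
        assert abs(es) < 0.25
        assert es == pytest.approx(
            self.hand_stepped_es(metric, {0, 5, 10, 15, 20}, weight=0.0),
            abs=1e-12,
        )


class TestGsea:
    @pytest.fixture(scope="class")
    def ds(self):
        return synthetic.generate_base(31)

    def test_es_sign_flips_with_comparison(self, ds):
        mapping = map_database(ds.database, ds.annotations, ds.matrix)
        fwd = gsea(ds.matrix, ds.database, mapping, ("case", "control"),
                   n_perm=100, seed=1).set_index("set_id")
        rev = gsea(ds.matrix, ds.database, mapping, ("control", "case"),
                   n_perm=100, seed=1).set_index("set_id")
        planted = sorted(ds.truth)
        np.testing.assert_allclose(
            fwd.loc[planted, "es"], -rev.loc[planted, "es"], atol=1e-10
        )

    def test_deterministic_and_planted_enriched(self, ds):
        r1 = run_methods(ds, ["gsea"], n_perm_gsea=200, seed=6)["gsea"]
        r2 = run_methods(ds, ["gsea"], n_perm_gsea=200, seed=6)["gsea"]
        assert r1 == r2
        big = [r1[s] for s in ("Twenty", "Forty", "Eighty")]
        bg = [p for s, p in r1.items() if s.startswith("BG")]
        assert max(big) < np.median(bg)

    def test_set_as_large_as_ranked_list_rejected(self):
        m = _matrix(np.random.default_rng(0).standard_normal((4, 8)).tolist())
        with pytest.raises(ValueError):
            enrichment_score(np.ones(4), np.arange(4))
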