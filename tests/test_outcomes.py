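"""Survival screens, host-gene screens and gene-set enrichment."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from microseek.cohort import PresenceMatrix
from microseek.outcomes import (
    geneset_enrichment,
    group_by_feature_union,
    host_gene_screen,
    km_curve,
    logrank_test,
    survival_screen,
    zscore_expression,
)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        t = [5, 8, 12, 20, 25, 30.0] * 2
        e = [1, 1, 0, 1, 0, 1] * 2
        g = [True] * 6 + [False] * 6
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(0.0, abs=1e-12) and p == pytest.approx(1.0)

    def test_twelve_patient_hand_computation(self):
        # step-by-step observed-minus-expected over the event times
        t = np.array([3, 5, 7, 9, 11, 13, 4, 6, 8, 10, 12, 14], dtype=float)
        e = np.array([1, 1, 0, 1, 1, 0, 1, 1, 1, 0, 1, 1])
        g = np.array([True] * 6 + [False] * 6)
        o_minus_e, var = 0.0, 0.0
        for et in np.unique(t[e == 1]):
            at = t >= et
            n, n1 = at.sum(), (at & g).sum()
            d = ((t == et) & (e == 1)).sum()
            d1 = ((t == et) & (e == 1) & g).sum()
            o_minus_e += d1 - d * n1 / n
            if n > 1:
                var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
        chi2, p = logrank_test(t, e, g)
        assert chi2 == pytest.approx(o_minus_e**2 / var, rel=1e-12)

    def test_agrees_with_lifelines_on_random_fixtures(self):
        from lifelines.statistics import logrank_test as ll

        rng = np.random.default_rng(13)
        for _ in range(50):
            n = int(rng.integers(20, 80))
            t = rng.exponential(50, n).round(2) + 1
            e = (rng.random(n) < 0.7).astype(int)
            g = rng.random(n) < 0.5
            if g.sum() in (0, n):
                continue
            chi2, p = logrank_test(t, e, g)
            ref = ll(t[g], t[~g], e[g], e[~g])
            assert p == pytest.approx(ref.p_value, abs=1e-8)

    def test_all_censored_undefined(self):
        chi2, p = logrank_test([5, 6, 7, 8.0], [0, 0, 0, 0], [True, True, False, False])
        assert chi2 == 0.0 and p == 1.0  # no events anywhere: no difference


class TestSurvivalScreen:
    @staticmethod
    def _fixture(n=40, seed=0):
        rng = np.random.default_rng(seed)
        patients = [f"P{i:04d}" for i in range(n)]
        pm = PresenceMatrix(
            pd.DataFrame({"COMMON": rng.random(n) < 0.5, "RARE": [True] * 4 + [False] * (n - 4)},
                         index=patients),
            pd.Series("case", index=patients), "protein")
        rows = []
        for endpoint in ("OS", "DFS"):
            for p in patients:
                rows.append((p, endpoint, float(rng.exponential(500) + 1), int(rng.random() < 0.8)))
        surv = pd.DataFrame(rows, columns=["patient_id", "endpoint", "time", "event"])
        return pm, surv

    def test_five_five_rule_skips_sparse_features(self):
        pm, surv = self._fixture()
        res = survival_screen(pm, surv).set_index(["feature", "endpoint"])
        assert not res.loc[("RARE", "OS"), "tested"]
        assert np.isnan(res.loc[("RARE", "OS"), "p"])
        assert res.loc[("COMMON", "OS"), "tested"]

    def test_fdr_within_endpoint_over_tested_only(self):
        pm, surv = self._fixture()
        res = survival_screen(pm, surv)
        tested = res[res.tested]
        assert tested["q"].notna().all()
        assert res.loc[~res.tested, "q"].isna().all()

    def test_patients_without_clinical_data_excluded(self):
        pm, surv = self._fixture()
        trimmed = surv[surv.patient_id != "P0000"]
        res = survival_screen(pm, trimmed).set_index(["feature", "endpoint"])
        assert res.loc[("COMMON", "OS"), "n_pos"] + res.loc[("COMMON", "OS"), "n_neg"] == 39


class TestKmCurve:
    def test_product_limit_hand_case(self):
        km = km_curve([2, 4, 4, 6, 8.0], [1, 1, 0, 1, 0])
        # S(2) = 4/5, S(4) = 4/5 * 3/4, S(6) = ... * 1/2
        assert km["survival"].tolist() == pytest.approx([1.0, 0.8, 0.6, 0.3])
        assert km["at_risk"].tolist() == [5, 5, 4, 2]


class TestHostGeneScreen:
    @staticmethod
    def _expr(n=30, seed=1):
        rng = np.random.default_rng(seed)
        patients = [f"P{i:04d}" for i in range(2 * n)]
        groups = pd.Series([True] * n + [False] * n, index=patients)
        up = np.r_[rng.normal(1.0, 0.1, n), rng.normal(-0.5, 0.1, n)]
        null = rng.normal(0, 1, 2 * n)
        expr = pd.DataFrame([up, null], index=["UP", "NULL"], columns=patients)
        return expr, groups

    def test_three_rule_conjunction(self):
        expr, groups = self._expr()
        res = host_gene_screen(expr, groups).set_index("gene")
        assert bool(res.loc["UP", "selected"])
        assert not bool(res.loc["NULL", "selected"])

    def test_low_median_z_blocks_selection_despite_small_p(self):
        # a noisy but significant gene whose positive-group median z stays
        # under the 0.2 default is rejected by the conjunction
        rng = np.random.default_rng(7)
        n = 200
        patients = [f"P{i:04d}" for i in range(2 * n)]
        groups = pd.Series([True] * n + [False] * n, index=patients)
        weak = np.r_[rng.normal(0.3, 1.0, n), rng.normal(0.0, 1.0, n)]
        expr = pd.DataFrame([weak], index=["WEAK"], columns=patients)
        res = host_gene_screen(expr, groups).set_index("gene")
        assert res.loc["WEAK", "p"] < 0.05
        assert res.loc["WEAK", "median_z_pos"] < 0.2
        assert not bool(res.loc["WEAK", "selected"])

    def test_constant_gene_never_selected(self):
        expr, groups = self._expr()
        expr.loc["CONST"] = 3.14
        res = host_gene_screen(expr, groups).set_index("gene")
        assert res.loc["CONST", "p"] == 1.0 and not bool(res.loc["CONST", "selected"])

    def test_invariant_to_monotone_rescaling(self):
        expr, groups = self._expr()
        a = host_gene_screen(expr, groups).set_index("gene")["selected"]
        rescaled = expr.mul(pd.Series([7.0, 0.3], index=expr.index), axis=0) \
                       .add(pd.Series([5.0, -2.0], index=expr.index), axis=0)
        b = host_gene_screen(rescaled, groups).set_index("gene")["selected"]
        assert a.equals(b)

    def test_zscores_standardized(self):
        expr, _ = self._expr()
        z = zscore_expression(expr)
        assert np.allclose(z.mean(axis=1), 0, atol=1e-9)
        assert np.allclose(z.std(axis=1, ddof=0), 1, atol=1e-6)


class TestGenesetEnrichment:
    UNIVERSE = [f"g{i}" for i in range(20)]

    def test_hypergeometric_hand_case(self):
        # universe 20, set 5, selection 10, overlap 4 -> P(X >= 4) ~ 0.1517
        selection = self.UNIVERSE[:10]
        gene_set = self.UNIVERSE[6:10] + ["g15"]
        res = geneset_enrichment(selection, {"S": gene_set}, self.UNIVERSE)
        expected = stats.hypergeom.sf(3, 20, 5, 10)
        assert res.loc[0, "p"] == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.1517, abs=1e-4)

    def test_disjoint_set_p_one(self):
        res = geneset_enrichment(self.UNIVERSE[:5], {"S": self.UNIVERSE[10:15]}, self.UNIVERSE)
        assert res.loc[0, "p"] == 1.0

    def test_selection_equals_set_is_minimal_p(self):
        sel = self.UNIVERSE[:5]
        p_exact = geneset_enrichment(sel, {"S": sel}, self.UNIVERSE).loc[0, "p"]
        for other in (self.UNIVERSE[:4] + ["g10"], self.UNIVERSE[1:6]):
            alt = geneset_enrichment(other, {"S": sel}, self.UNIVERSE).loc[0, "p"]
            assert p_exact <= alt
        assert p_exact == pytest.approx(stats.hypergeom.sf(4, 20, 5, 5), rel=1e-12)

    def test_empty_selection_all_p_one(self):
        res = geneset_enrichment([], {"S": self.UNIVERSE[:5]}, self.UNIVERSE)
        assert (res["p"] == 1.0).all()


class TestFeatureUnion:
    def _pm(self):
        patients = [f"P{i}" for i in range(10)]
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.random((10, 3)) < 0.4, index=patients, columns=["A", "B", "C"])
        return PresenceMatrix(df, pd.Series("case", index=patients), "protein")

    def test_single_feature_identity(self):
        pm = self._pm()
        assert group_by_feature_union(pm, ["B"]).equals(pm.data["B"])

    def test_or_semantics_matches_brute_force(self):
        pm = self._pm()
        g = group_by_feature_union(pm, ["A", "B", "C"])
        for p in pm.data.index:
            assert g[p] == (pm.data.loc[p, "A"] or pm.data.loc[p, "B"] or pm.data.loc[p, "C"])

    def test_empty_list_raises(self):
        with pytest.raises(ValueError):
            group_by_feature_union(self._pm(), [])
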