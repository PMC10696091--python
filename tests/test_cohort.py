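"""Prevalence statistics: pooling, filtering, binomial tails, BH FDR,
propensity fitting and the weighted chi-squared."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from microseek import simulate as sim
from microseek.cohort import (
    IPWConfig,
    PresenceMatrix,
    bh_fdr,
    binomial_prevalence_test,
    build_matrix,
    filter_features,
    fit_propensity,
    ipw_weights,
    prevalence_analysis,
    weighted_chisq,
    weighted_smd,
)


def make_pm(data, cohorts, kind="genus"):
    df = pd.DataFrame(data).astype(bool)
    return PresenceMatrix(df, pd.Series(cohorts, index=df.index), kind)


class TestBuildMatrix:
    def test_or_pooling_across_samples(self):
        per_sample = pd.DataFrame({"G": [True, False]}, index=["s1", "s2"])
        pm = build_matrix(per_sample, {"s1": "p1", "s2": "p1"}, {"p1": "case"})
        assert bool(pm.data.loc["p1", "G"])

    def test_identity_when_one_sample_per_patient(self):
        per_sample = pd.DataFrame({"G": [True, False], "H": [False, True]}, index=["s1", "s2"])
        pm = build_matrix(per_sample, {"s1": "p1", "s2": "p2"}, {"p1": "case", "p2": "control"})
        assert pm.data.loc["p1", "G"] and not pm.data.loc["p1", "H"]
        assert pm.data.loc["p2", "H"] and not pm.data.loc["p2", "G"]

    def test_matches_exhaustive_hand_pooling(self):
        rng = np.random.default_rng(1)
        samples = [f"s{i}" for i in range(6)]
        mapping = {s: f"p{i // 2}" for i, s in enumerate(samples)}
        per_sample = pd.DataFrame(rng.random((6, 4)) < 0.5, index=samples,
                                  columns=list("ABCD"))
        pm = build_matrix(per_sample, mapping, {f"p{i}": "case" for i in range(3)})
        for pid in ("p0", "p1", "p2"):
            rows = [s for s in samples if mapping[s] == pid]
            for f in "ABCD":
                assert pm.data.loc[pid, f] == per_sample.loc[rows, f].any()

    def test_unmapped_sample_raises(self):
        per_sample = pd.DataFrame({"G": [True]}, index=["s1"])
        with pytest.raises(KeyError):
            build_matrix(per_sample, {}, {})


class TestFilterFeatures:
    def test_boundary_at_least_ten_percent_kept(self):
        data = {"F": [True] + [False] * 9 + [False] * 10}
        pm = make_pm(data, ["case"] * 10 + ["control"] * 10)
        assert filter_features(pm) == ["F"]

    def test_below_threshold_dropped(self):
        # 9% in both cohorts (well under 10%)
        data = {"F": ([True] * 9 + [False] * 91) * 2}
        pm = make_pm(data, ["case"] * 100 + ["control"] * 100)
        assert filter_features(pm, 0.10) == []

    def test_matches_hand_computation_on_toy_matrix(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.random((20, 5)) < 0.25, columns=list("ABCDE"))
        cohorts = ["case"] * 8 + ["control"] * 12
        pm = make_pm(df, cohorts)
        expected = [
            f for f in "ABCDE"
            if df.iloc[:8][f].mean() >= 0.1 or df.iloc[8:][f].mean() >= 0.1
        ]
        assert filter_features(pm) == expected


class TestBinomialTest:
    def test_zero_prevalence_clamped(self):
        # p0 clamps to 1e-4: P(X <= 0) = (1 - 1e-4)^161
        p = binomial_prevalence_test(0, 161, 0.0, "less")
        assert p == pytest.approx((1 - 1e-4) ** 161, rel=1e-12)

    def test_all_cases_positive_greater(self):
        p = binomial_prevalence_test(20, 20, 0.5, "greater")
        assert p == pytest.approx(0.5**20, rel=1e-12)

    def test_grid_matches_pmf_summation(self):
        # exhaustive oracle over (k, n, p0) including the clamp endpoints
        for n in (1, 5, 12, 30):
            for p0 in (0.0, 1e-4, 0.2, 0.5, 0.97, 0.9999, 1.0):
                pc = min(max(p0, 1e-4), 1 - 1e-4)
                pmf = np.array([stats.binom.pmf(i, n, pc) for i in range(n + 1)])
                for k in range(n + 1):
                    assert binomial_prevalence_test(k, n, p0, "greater") == \
                        pytest.approx(pmf[k:].sum(), abs=1e-12)
                    assert binomial_prevalence_test(k, n, p0, "less") == \
                        pytest.approx(pmf[: k + 1].sum(), abs=1e-12)

    def test_monotone_in_k_for_greater(self):
        ps = [binomial_prevalence_test(k, 30, 0.3, "greater") for k in range(31)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_direction_raises(self):
        with pytest.raises(ValueError):
            binomial_prevalence_test(1, 10, 0.5, "two-sided")


class TestBhFdr:
    def test_single_p_identity(self):
        assert bh_fdr([0.04]) == pytest.approx([0.04])

    def test_hand_step_up(self):
        assert bh_fdr([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])
        assert bh_fdr([0.01, 0.04, 0.9]) == pytest.approx([0.03, 0.06, 0.9])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_permutation_invariant_and_dominates_p(self, ps):
        q = bh_fdr(ps)
        assert (q >= np.asarray(ps) - 1e-12).all()
        perm = np.random.default_rng(0).permutation(len(ps))
        q_perm = bh_fdr(np.asarray(ps)[perm])
        assert np.allclose(np.sort(q), np.sort(q_perm))


class TestPrevalenceAnalysis:
    def test_directions_follow_prevalence_difference(self):
        data = {"UP": [True] * 8 + [False] * 2 + [True] * 2 + [False] * 8,
                "DOWN": [True] * 2 + [False] * 8 + [True] * 8 + [False] * 2}
        pm = make_pm(data, ["case"] * 10 + ["control"] * 10)
        res = prevalence_analysis(pm).set_index("feature")
        assert res.loc["UP", "direction"] == "greater"
        assert res.loc["DOWN", "direction"] == "less"
        assert res.loc["UP", "p"] < 0.05


class TestPropensity:
    def test_null_covariates_auc_near_half(self):
        cov, _ = sim.make_cohort(sim.CohortSpec(250, 250, {}, {}, 0.2, 5))
        _, auc = fit_propensity(cov, cov["cohort"], IPWConfig(rng_seed=0))
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_perfect_separator_auc_one(self):
        n = 100
        cov = pd.DataFrame({
            "age": np.r_[np.full(n, 80.0), np.full(n, 30.0)],
            "weight": np.full(2 * n, 70.0), "seq_depth": np.full(2 * n, 5e7),
            "sex": 0, "smoking": 0, "race": "white",
        }, index=[f"P{i:04d}" for i in range(2 * n)])
        labels = pd.Series(["case"] * n + ["control"] * n, index=cov.index)
        _, auc = fit_propensity(cov, labels, IPWConfig(rng_seed=0))
        assert auc > 0.99

    def test_recovers_true_propensity_ranking(self):
        # 1.0 SD shift on age: fitted probabilities track the true propensity
        cov, _ = sim.make_cohort(sim.CohortSpec(300, 300, {"age": 1.0}, {}, 0.2, 7))
        prop, _ = fit_propensity(cov, cov["cohort"], IPWConfig(rng_seed=0))
        z = (cov["age"] - 55.0) / 12.0
        true_p = 1 / (1 + np.exp(-(1.0 * z - 0.5)))
        rho = stats.spearmanr(prop, true_p).statistic
        assert rho > 0.8

    def test_constant_label_raises(self):
        cov, _ = sim.make_cohort(sim.CohortSpec(5, 5, {}, {}, 0.2, 8))
        with pytest.raises(ValueError):
            fit_propensity(cov, pd.Series("case", index=cov.index), IPWConfig())


class TestWeightedChisq:
    def test_unit_weights_match_closed_form(self):
        # table [[10,20],[20,10]]: chi2 = n(ad-bc)^2 / prod(margins) = 20/3
        pres = np.array([True] * 10 + [False] * 20 + [True] * 20 + [False] * 10)
        is_case = np.array([True] * 30 + [False] * 30)
        chi2, p = weighted_chisq(pres, is_case, np.ones(60))
        assert chi2 == pytest.approx(20 / 3, rel=1e-12)
        assert p == pytest.approx(stats.chi2.sf(20 / 3, 1), rel=1e-12)

    def test_zero_margin_undefined(self):
        pres = np.zeros(20, dtype=bool)
        is_case = np.array([True] * 10 + [False] * 10)
        chi2, p = weighted_chisq(pres, is_case, np.ones(20))
        assert np.isnan(chi2) and np.isnan(p)

    def test_type_one_error_without_confounding(self):
        rng = np.random.default_rng(9)
        rej = []
        for _ in range(500):
            pres = rng.random(200) < 0.4
            is_case = np.r_[np.ones(100, bool), np.zeros(100, bool)]
            _, p = weighted_chisq(pres, is_case, np.ones(200))
            rej.append(p < 0.05)
        assert 0.03 <= np.mean(rej) <= 0.08

    def test_ipw_balances_confounded_covariates(self):
        cov, _ = sim.make_cohort(sim.CohortSpec(200, 200, {"age": 1.0}, {}, 0.2, 11))
        prop, _ = fit_propensity(cov, cov["cohort"], IPWConfig(rng_seed=1))
        w = ipw_weights(prop, cov["cohort"])
        raw = weighted_smd(cov[["age", "weight", "seq_depth"]], cov["cohort"],
                           pd.Series(1.0, index=cov.index))
        balanced = weighted_smd(cov[["age", "weight", "seq_depth"]], cov["cohort"], w)
        assert raw["age"] > 0.8
        assert balanced.max() < 0.15
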