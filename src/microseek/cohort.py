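"""Cohort prevalence statistics.

Two analyses over a boolean patients x features presence matrix:

* a one-tailed binomial test per feature, with the control-cohort prevalence
  as the null probability clamped to [0.0001, 0.9999] (exactly 0 or 1 would
  force p = 0), direction chosen by the sign of the case-control prevalence
  difference, Benjamini-Hochberg FDR across features; features must first
  reach 10% prevalence in at least one cohort;

* a confounder-corrected analysis: a boosted logistic regression on patient
  covariates estimates the propensity of case membership, observations are
  weighted by the inverse probability of their observed cohort, and a
  chi-squared test (df = 1) is run on the weight-summed 2x2 table.  The IPW
  path tests all features with any prevalence (no 10% filter).

Four standard guards keep the corrected analysis calibrated: propensities
are cross-fitted (each patient scored by a model not trained on them, which
stops in-sample boosting from overfitting the weights); the number of
boosting iterations is chosen by the covariate-balance criterion (the
iteration whose weights minimize the maximum standardized mean difference,
as in the twang approach to boosted propensity scores) rather than by
deviance; weights are stabilized by the observed-group marginal probability
so they sum to about the sample size; and each cohort row of the weighted
table is rescaled to that group's Kish effective sample size before the
chi-squared reference is applied (weight-summed cells are not multinomial
counts — the variance of a weighted proportion is p(1-p)/ESS of its own
group, and without the rescaling the test is anti-conservative).  Each
guard can be switched off in :class:`IPWConfig`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from statsmodels.stats.multitest import multipletests

P0_MIN, P0_MAX = 0.0001, 0.9999


@dataclass
class PresenceMatrix:
    """Boolean patients x features matrix with a case/control label per patient."""

    data: pd.DataFrame  # bool, index = patient_id
    cohort: pd.Series  # "case" / "control", same index
    kind: str = "genus"  # genus | species | protein

    def __post_init__(self) -> None:
        self.data = self.data.astype(bool)
        self.cohort = self.cohort.reindex(self.data.index)
        if self.cohort.isna().any():
            raise ValueError("every patient needs a cohort label")
        bad = set(self.cohort.unique()) - {"case", "control"}
        if bad:
            raise ValueError(f"unknown cohort labels: {sorted(bad)}")

    @property
    def cases(self) -> pd.DataFrame:
        return self.data[self.cohort == "case"]

    @property
    def controls(self) -> pd.DataFrame:
        return self.data[self.cohort == "control"]


def build_matrix(
    per_sample: pd.DataFrame,
    sample_to_patient: dict[str, str],
    cohort_labels: dict[str, str],
    kind: str = "genus",
) -> PresenceMatrix:
    """OR-pool per-sample presence to the patient level.

    A patient is positive for a feature iff any of their samples is.
    """
    missing = [s for s in per_sample.index if s not in sample_to_patient]
    if missing:
        raise KeyError(f"samples without a patient mapping: {missing[:5]}")
    patients = per_sample.index.map(sample_to_patient)
    pooled = per_sample.astype(bool).groupby(patients).any()
    pooled.index.name = "patient_id"
    unlabeled = [p for p in pooled.index if p not in cohort_labels]
    if unlabeled:
        raise KeyError(f"patients without a cohort label: {unlabeled[:5]}")
    cohort = pd.Series({p: cohort_labels[p] for p in pooled.index}, name="cohort")
    return PresenceMatrix(pooled, cohort, kind)


def filter_features(matrix: PresenceMatrix, min_prevalence: float = 0.10) -> list[str]:
    """Features reaching min_prevalence in cases OR in controls."""
    prev_case = matrix.cases.mean(axis=0)
    prev_ctrl = matrix.controls.mean(axis=0)
    keep = (prev_case >= min_prevalence) | (prev_ctrl >= min_prevalence)
    return [f for f in matrix.data.columns if keep[f]]


def binomial_prevalence_test(
    k_case: int, n_case: int, prevalence_control: float, direction: str
) -> float:
    """One-tailed binomial tail with the clamped control prevalence as null."""
    if not (0 <= k_case <= n_case):
        raise ValueError("k_case must be in [0, n_case]")
    if not (0.0 <= prevalence_control <= 1.0):
        raise ValueError("prevalence_control must be in [0, 1]")
    p0 = min(max(prevalence_control, P0_MIN), P0_MAX)
    if direction == "greater":
        return float(stats.binom.sf(k_case - 1, n_case, p0))
    if direction == "less":
        return float(stats.binom.cdf(k_case, n_case, p0))
    raise ValueError(f"direction must be 'greater' or 'less', got {direction!r}")


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def prevalence_analysis(
    matrix: PresenceMatrix, min_prevalence: float = 0.10
) -> pd.DataFrame:
    """Per-feature one-tailed binomial prevalence comparison with BH FDR."""
    features = filter_features(matrix, min_prevalence)
    cases, controls = matrix.cases, matrix.controls
    n_case = len(cases)
    rows = []
    for f in features:
        k = int(cases[f].sum())
        prev_ctrl = float(controls[f].mean())
        direction = "greater" if k / n_case >= prev_ctrl else "less"
        p = binomial_prevalence_test(k, n_case, prev_ctrl, direction)
        rows.append((f, matrix.kind, k, int(controls[f].sum()), prev_ctrl, direction, p))
    out = pd.DataFrame(
        rows,
        columns=["feature", "kind", "n_case_present", "n_control_present",
                 "prevalence_control", "direction", "p"],
    )
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    out["analysis"] = "binomial"
    return out


# ---------------------------------------------------------------------------
# Confounder-corrected analysis
# ---------------------------------------------------------------------------


@dataclass
class IPWConfig:
    covariates: list[str] = field(
        default_factory=lambda: ["race", "age", "sex", "weight", "smoking", "seq_depth"]
    )
    boosting_rounds: int = 800  # upper bound; balance selection picks the stage
    learning_rate: float = 0.05
    max_depth: int = 1  # additive stumps: low-variance propensity surface
    cross_fit_folds: int = 5  # 0 disables cross-fitting (in-sample propensities)
    balance_selection: bool = True  # pick the iteration minimizing max SMD
    selection_step: int = 25  # candidate iterations are multiples of this
    stabilized_weights: bool = True
    truncation_quantiles: tuple[float, float] = (0.01, 0.99)
    effective_sample_size: bool = True
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.covariates:
            raise ValueError("covariates must be non-empty")


def _design(covariate_table: pd.DataFrame, covariates: list[str]) -> pd.DataFrame:
    x = covariate_table[covariates].copy()
    cat = [c for c in covariates if x[c].dtype == object or str(x[c].dtype) == "category"]
    return pd.get_dummies(x, columns=cat, drop_first=True).astype(float)


def fit_propensity(
    covariate_table: pd.DataFrame, cohort_labels: pd.Series, config: IPWConfig | None = None
) -> tuple[pd.Series, float]:
    """Boosted-logistic propensity of case membership; returns (P(case), AUC).

    Patients with incomplete covariates must be excluded beforehand.
    """
    config = config or IPWConfig()
    y = (cohort_labels.reindex(covariate_table.index) == "case").astype(int)
    if y.nunique() < 2:
        raise ValueError("cohort labels are constant; cannot fit a propensity model")
    x = _design(covariate_table, config.covariates)
    if x.isna().any().any():
        raise ValueError("covariates contain missing values; exclude those patients first")

    def make_model():
        return GradientBoostingClassifier(
            n_estimators=config.boosting_rounds,
            learning_rate=config.learning_rate,
            max_depth=config.max_depth,
            random_state=config.rng_seed,
        )

    xv, yv = x.to_numpy(), y.to_numpy()
    step = config.selection_step if config.balance_selection else config.boosting_rounds
    stages = list(range(step, config.boosting_rounds + 1, step)) or [config.boosting_rounds]

    def staged_probs(model, x_pred):
        """Probabilities at each candidate stage, shape (n_stages, n)."""
        out = np.empty((len(stages), len(x_pred)))
        for i, sp in enumerate(model.staged_predict_proba(x_pred)):
            k = i + 1
            if k % step == 0 and k // step <= len(stages):
                out[k // step - 1] = sp[:, 1]
        return out

    # cross-fitting needs at least `folds` members per class; degrade to an
    # in-sample fit on tiny cohorts rather than failing
    n_folds = min(config.cross_fit_folds or 0, int(np.bincount(yv).min()))
    probs = np.empty((len(stages), len(yv)))
    if n_folds > 1:
        from sklearn.model_selection import StratifiedKFold

        folds = StratifiedKFold(n_folds, shuffle=True, random_state=config.rng_seed)
        for train_idx, test_idx in folds.split(xv, yv):
            model = make_model()
            model.fit(xv[train_idx], yv[train_idx])
            probs[:, test_idx] = staged_probs(model, xv[test_idx])
    else:
        model = make_model()
        model.fit(xv, yv)
        probs = staged_probs(model, xv)

    if len(stages) > 1:
        # balance criterion: keep the stage whose weights best balance the
        # covariates (smallest maximum standardized mean difference)
        best_idx, best_smd = 0, np.inf
        for i in range(len(stages)):
            p_i = pd.Series(np.clip(probs[i], 1e-6, 1 - 1e-6),
                            index=covariate_table.index)
            w_i = ipw_weights(p_i, cohort_labels, config.truncation_quantiles,
                              config.stabilized_weights)
            smd = _smd_from_design(x, yv, w_i.to_numpy()).max()
            if smd < best_smd:
                best_idx, best_smd = i, smd
        p = probs[best_idx]
    else:
        p = probs[-1]

    p = np.clip(p, 1e-6, 1 - 1e-6)
    auc = float(roc_auc_score(y, p))
    return pd.Series(p, index=covariate_table.index, name="propensity"), auc


def ipw_weights(
    propensity: pd.Series, cohort_labels: pd.Series,
    truncation_quantiles: tuple[float, float] = (0.01, 0.99),
    stabilized: bool = True,
) -> pd.Series:
    """1 / P(observed cohort), optionally stabilized, truncated at quantiles.

    Stabilization multiplies by the observed group's marginal probability so
    the weights sum to approximately the number of patients.
    """
    is_case = (cohort_labels.reindex(propensity.index) == "case").to_numpy()
    w = np.where(is_case, 1.0 / propensity, 1.0 / (1.0 - propensity))
    if stabilized:
        w *= np.where(is_case, is_case.mean(), 1 - is_case.mean())
    lo, hi = np.quantile(w, truncation_quantiles)
    return pd.Series(np.clip(w, lo, hi), index=propensity.index, name="weight")


def weighted_chisq(
    presence: np.ndarray, is_case: np.ndarray, weights: np.ndarray,
    effective_sample_size: bool = True,
) -> tuple[float, float]:
    """Chi-squared (df=1) on the weight-summed 2x2 cohort x presence table.

    Returns (statistic, p).  With ``effective_sample_size`` each cohort row
    is rescaled to its group's Kish effective sample size, matching the
    variance p(1-p)/ESS_g of a weighted proportion; with unit weights the
    rescaling is a no-op and the statistic is the plain Pearson chi-squared
    without continuity correction.  A zero weighted margin makes the
    statistic undefined -> (nan, nan).
    """
    presence = np.asarray(presence, dtype=bool)
    is_case = np.asarray(is_case, dtype=bool)
    w = np.asarray(weights, dtype=float)
    table = np.array(
        [
            [w[is_case & presence].sum(), w[is_case & ~presence].sum()],
            [w[~is_case & presence].sum(), w[~is_case & ~presence].sum()],
        ]
    )
    if np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        return float("nan"), float("nan")
    if effective_sample_size:
        for gi, mask in enumerate((is_case, ~is_case)):
            wg = w[mask]
            ess_g = wg.sum() ** 2 / np.sum(wg**2)
            table[gi] = table[gi] / table[gi].sum() * ess_g
    row = table.sum(axis=1)
    col = table.sum(axis=0)
    if np.any(col == 0):
        return float("nan"), float("nan")
    expected = np.outer(row, col) / table.sum()
    chi2 = float(np.sum((table - expected) ** 2 / expected))
    return chi2, float(stats.chi2.sf(chi2, df=1))


def ipw_analysis(
    matrix: PresenceMatrix,
    covariate_table: pd.DataFrame,
    config: IPWConfig | None = None,
) -> tuple[pd.DataFrame, float]:
    """Confounder-corrected prevalence comparison for every feature.

    Returns (results table, propensity AUC).  All features with any
    prevalence are tested; features with an undefined statistic are kept
    with missing p/q.
    """
    config = config or IPWConfig()
    common = matrix.data.index.intersection(covariate_table.index)
    data = matrix.data.loc[common]
    cohort = matrix.cohort.loc[common]
    propensity, auc = fit_propensity(covariate_table.loc[common], cohort, config)
    weights = ipw_weights(propensity, cohort, config.truncation_quantiles, config.stabilized_weights)
    is_case = (cohort == "case").to_numpy()
    w = weights.to_numpy()
    rows = []
    for f in data.columns:
        pres = data[f].to_numpy()
        if pres.sum() == 0:
            continue
        chi2, p = weighted_chisq(pres, is_case, w, config.effective_sample_size)
        # direction of the weighted prevalence difference (the test itself
        # is two-sided)
        prev_case = np.average(pres[is_case], weights=w[is_case])
        prev_ctrl = np.average(pres[~is_case], weights=w[~is_case])
        direction = "greater" if prev_case >= prev_ctrl else "less"
        rows.append((f, matrix.kind, int(pres[is_case].sum()), int(pres[~is_case].sum()),
                     direction, chi2, p))
    out = pd.DataFrame(
        rows, columns=["feature", "kind", "n_case_present", "n_control_present",
                       "direction", "chi2", "p"]
    )
    out["q"] = np.nan
    tested = out["p"].notna()
    if tested.any():
        out.loc[tested, "q"] = bh_fdr(out.loc[tested, "p"].to_numpy())
    out["analysis"] = "ipw_chisq"
    return out, auc


def _smd_from_design(x: pd.DataFrame, y: np.ndarray, w: np.ndarray) -> pd.Series:
    """Weighted standardized mean differences over a numeric design matrix."""
    is_case = y.astype(bool)
    out = {}
    for c in x.columns:
        v = x[c].to_numpy(dtype=float)
        m1 = np.average(v[is_case], weights=w[is_case])
        m0 = np.average(v[~is_case], weights=w[~is_case])
        s1 = np.average((v[is_case] - m1) ** 2, weights=w[is_case])
        s0 = np.average((v[~is_case] - m0) ** 2, weights=w[~is_case])
        pooled = np.sqrt((s1 + s0) / 2)
        out[c] = 0.0 if pooled == 0 else abs(m1 - m0) / pooled
    return pd.Series(out, name="smd")


def weighted_smd(
    covariate_table: pd.DataFrame, cohort_labels: pd.Series, weights: pd.Series,
    covariates: list[str] | None = None,
) -> pd.Series:
    """Weighted standardized mean difference per covariate (balance diagnostic)."""
    x = _design(covariate_table, covariates or list(covariate_table.columns))
    y = (cohort_labels.reindex(x.index) == "case").to_numpy()
    return _smd_from_design(x, y, weights.reindex(x.index).to_numpy())
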