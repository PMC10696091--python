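"""Outcome statistics: survival screens and host-expression screens.

Microbial features (species / genus / protein family) are screened for
survival association with a two-group log-rank test per endpoint (overall
and disease-free), testing only features with at least 5 positive and 5
negative patients, with BH FDR per endpoint over the tested features.

Host genes are screened for association with a designated microbial-feature
group by a two-sided rank-sum test plus median z-score criteria, and the
resulting gene list can be tested for over-representation in user-supplied
gene sets with a one-sided hypergeometric tail.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import PresenceMatrix, bh_fdr

ENDPOINTS = ("OS", "DFS")


# ---------------------------------------------------------------------------
# Log-rank
# ---------------------------------------------------------------------------


def logrank_test(times, events, groups) -> tuple[float, float]:
    """Two-group log-rank statistic and p-value.

    At each distinct event time the observed-minus-expected event count in
    group 1 is accumulated with its hypergeometric variance; the squared sum
    over its variance is chi-squared with 1 df.  Identical survival in both
    groups gives statistic 0, p = 1; zero total variance (e.g. everything
    censored) is undefined -> (nan, nan).
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups, dtype=bool)
    event_times = np.unique(t[e == 1])
    o_minus_e = 0.0
    var = 0.0
    for et in event_times:
        at_risk = t >= et
        n = at_risk.sum()
        n1 = (at_risk & g).sum()
        d = ((t == et) & (e == 1)).sum()
        d1 = ((t == et) & (e == 1) & g).sum()
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += d * (n1 / n) * (1 - n1 / n) * (n - d) / (n - 1)
    if var == 0:
        if o_minus_e == 0:
            return 0.0, 1.0
        return float("nan"), float("nan")
    chi2 = o_minus_e**2 / var
    return float(chi2), float(stats.chi2.sf(chi2, df=1))


def survival_screen(
    matrix: PresenceMatrix,
    survival: pd.DataFrame,
    endpoints: tuple[str, ...] = ENDPOINTS,
    min_pos: int = 5,
    min_neg: int = 5,
) -> pd.DataFrame:
    """Presence-based log-rank screen per feature and endpoint.

    ``survival`` columns: patient_id, endpoint, time, event.  Patients absent
    from the survival table (no clinical data) are excluded.  Features with
    fewer than ``min_pos`` positive or ``min_neg`` negative patients are
    reported untested; BH FDR runs per endpoint over tested features only.
    """
    rows = []
    for endpoint in endpoints:
        sub = survival[survival["endpoint"] == endpoint].set_index("patient_id")
        patients = matrix.data.index.intersection(sub.index)
        data = matrix.data.loc[patients]
        t = sub.loc[patients, "time"].to_numpy()
        e = sub.loc[patients, "event"].to_numpy()
        for f in data.columns:
            pos = data[f].to_numpy()
            n_pos, n_neg = int(pos.sum()), int((~pos).sum())
            if n_pos < min_pos or n_neg < min_neg:
                rows.append((f, endpoint, n_pos, n_neg, False, np.nan, np.nan, np.nan))
                continue
            chi2, p = logrank_test(t, e, pos)
            rows.append((f, endpoint, n_pos, n_neg, True, chi2, p, np.nan))
    out = pd.DataFrame(
        rows, columns=["feature", "endpoint", "n_pos", "n_neg", "tested", "chi2", "p", "q"]
    )
    for endpoint in endpoints:
        mask = (out["endpoint"] == endpoint) & out["tested"] & out["p"].notna()
        if mask.any():
            out.loc[mask, "q"] = bh_fdr(out.loc[mask, "p"].to_numpy())
    return out


def km_curve(times, events) -> pd.DataFrame:
    """Kaplan-Meier product-limit estimate as (time, at_risk, survival) rows."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    order = np.argsort(t)
    t, e = t[order], e[order]
    rows = [(0.0, len(t), 1.0)]
    surv = 1.0
    for et in np.unique(t[e == 1]):
        n = int((t >= et).sum())
        d = int(((t == et) & (e == 1)).sum())
        surv *= 1 - d / n
        rows.append((float(et), n, surv))
    return pd.DataFrame(rows, columns=["time", "at_risk", "survival"])


# ---------------------------------------------------------------------------
# Host expression
# ---------------------------------------------------------------------------


def zscore_expression(expression: pd.DataFrame) -> pd.DataFrame:
    """Per-gene z-scores across patients (genes x patients in, same shape out)."""
    mu = expression.mean(axis=1)
    sd = expression.std(axis=1, ddof=0)
    sd = sd.replace(0, np.nan)
    return expression.sub(mu, axis=0).div(sd, axis=0).fillna(0.0)


def host_gene_screen(
    expression: pd.DataFrame,
    group_labels: pd.Series,
    p_max: float = 0.05,
    z_pos_min: float = 0.2,
    z_neg_max: float = 0.0,
) -> pd.DataFrame:
    """Rank-sum screen for genes upregulated in the positive patient group.

    A gene is selected iff the two-sided rank-sum p-value is below ``p_max``
    (unadjusted), the median z-score in the positive group exceeds
    ``z_pos_min``, and the median z-score in the negative group is below
    ``z_neg_max``.  Constant genes get p = 1 and are never selected.
    """
    groups = group_labels.reindex(expression.columns).astype(bool)
    if groups.sum() < 2 or (~groups).sum() < 2:
        raise ValueError("need at least 2 patients per group")
    z = zscore_expression(expression)
    pos_cols = expression.columns[groups.to_numpy()]
    neg_cols = expression.columns[~groups.to_numpy()]
    rows = []
    for gene in expression.index:
        a = expression.loc[gene, pos_cols].to_numpy(dtype=float)
        b = expression.loc[gene, neg_cols].to_numpy(dtype=float)
        if np.ptp(np.concatenate([a, b])) == 0:
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic").pvalue)
        med_pos = float(np.median(z.loc[gene, pos_cols]))
        med_neg = float(np.median(z.loc[gene, neg_cols]))
        selected = (p < p_max) and (med_pos > z_pos_min) and (med_neg < z_neg_max)
        rows.append((gene, p, med_pos, med_neg, selected))
    return pd.DataFrame(rows, columns=["gene", "p", "median_z_pos", "median_z_neg", "selected"])


def geneset_enrichment(
    selected_genes, gene_sets: dict[str, list[str]], universe
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of each gene set, BH FDR."""
    universe = set(universe)
    selected = set(selected_genes)
    if not selected <= universe:
        raise ValueError("selected genes must be a subset of the universe")
    m = len(universe)
    n_sel = len(selected)
    rows = []
    for name, genes in gene_sets.items():
        members = set(genes) & universe
        overlap = len(members & selected)
        if n_sel == 0 or overlap == 0:
            p = 1.0
        else:
            p = float(stats.hypergeom.sf(overlap - 1, m, len(members), n_sel))
        rows.append((name, len(members), overlap, p))
    out = pd.DataFrame(rows, columns=["gene_set", "set_size", "overlap", "p"])
    out["q"] = bh_fdr(out["p"].to_numpy()) if len(out) else []
    return out


def group_by_feature_union(matrix: PresenceMatrix, features: list[str]) -> pd.Series:
    """Patient positive iff positive for at least one listed feature."""
    if not features:
        raise ValueError("feature list must be non-empty")
    missing = [f for f in features if f not in matrix.data.columns]
    if missing:
        raise KeyError(f"features not in presence matrix: {missing}")
    return matrix.data[features].any(axis=1)
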