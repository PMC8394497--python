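"""Univariate group comparisons with FDR control, and demographic tests.

Every feature column is compared between the stable (MCIs) and
progressing (MCIp) groups with the two-sided Wilcoxon rank-sum test;
p-values are adjusted within feature family (neuropsychological scores,
volumes, contralateral signal/texture) by the Benjamini-Hochberg step-up
procedure, and the top fraction of each family by raw p-value forms the
selection pool for the multivariate benchmark. Demographic comparability
uses Wilcoxon for age/education and a Yates-corrected chi-squared test
for the sex proportion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

Q_SIGNIFICANT = 0.05
# family -> fraction of lowest-p columns admitted to the multivariate pool
DEFAULT_POOL_FRACTIONS = {"signal_texture": 0.05, "volume": 0.15, "neuropsych": 1.0}


def wilcoxon_rank_sum(x, y) -> tuple:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Uses the exact null distribution when both samples have at most 10
    observations and the pooled data are tie-free; otherwise the normal
    approximation with tie and continuity correction.

    Returns (p_value, statistic, method) with method in
    {"exact", "asymptotic"}.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 observations")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        warnings.warn("all values identical across both groups; p = 1")
        return 1.0, float(x.size * y.size / 2.0), "degenerate"
    ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 10 and y.size <= 10 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided",
        method="exact" if method == "exact" else "asymptotic",
    )
    return float(res.pvalue), float(res.statistic), method


def benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` over the sorted p-values,
    capped at 1. Controls the FDR at level alpha when discoveries are
    declared at ``q < alpha``.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


@dataclass
class ScreenResult:
    results: pd.DataFrame          # feature, family, p, q, rank, direction, method
    pool: dict                     # family -> list of selected column names

    @property
    def pool_columns(self) -> list:
        return [c for cols in self.pool.values() for c in cols]


def _family_of(col: str, manifest_families: dict) -> str:
    if col.startswith("score_"):
        return "neuropsych"
    if col.endswith(".volume"):
        return "volume"
    return "signal_texture"


def screen_features(
    table: pd.DataFrame,
    pool_fractions: dict | None = None,
    group_col: str = "group",
    positive: str = "MCIp",
) -> ScreenResult:
    """Wilcoxon screening of every feature column with per-family BH control.

    Parameters
    ----------
    table : DataFrame
        Subjects x features with a ``group`` column. Constant columns get
        p = 1 and stay in the ranking.
    pool_fractions : dict, optional
        Fraction of each family's lowest-p columns admitted to the
        multivariate selection pool (default: 5% of signal/texture
        columns, 15% of volumes, all neuropsychological scores). Counts
        are ``floor(fraction * n_family)``, at least 1.

    Returns
    -------
    ScreenResult with the ranked per-feature results and the per-family
    pool of column names.
    """
    fractions = dict(DEFAULT_POOL_FRACTIONS)
    if pool_fractions:
        fractions.update(pool_fractions)
    groups = table[group_col]
    if groups.nunique() != 2:
        raise ValueError("need exactly two groups")
    pos = table[groups == positive]
    neg = table[groups != positive]
    if len(pos) < 2 or len(neg) < 2:
        raise ValueError("need at least 2 subjects per group")

    rows = []
    for col in table.columns.drop(group_col):
        fam = _family_of(col, {})
        x = pos[col].dropna().to_numpy(dtype=float)
        y = neg[col].dropna().to_numpy(dtype=float)
        if x.size < 2 or y.size < 2:
            p, stat, method = 1.0, np.nan, "insufficient"
        else:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                p, stat, method = wilcoxon_rank_sum(x, y)
        direction = positive if np.nanmedian(x) > np.nanmedian(y) else (
            "tie" if np.nanmedian(x) == np.nanmedian(y) else "other"
        )
        rows.append(
            {"feature": col, "family": fam, "p": p, "statistic": stat,
             "direction": direction, "method": method}
        )
    res = pd.DataFrame(rows)

    res["q"] = np.nan
    for fam, idx in res.groupby("family").groups.items():
        res.loc[idx, "q"] = benjamini_hochberg(res.loc[idx, "p"].to_numpy())
    res["significant"] = res["q"] < Q_SIGNIFICANT
    res = res.sort_values(["p", "feature"], kind="stable").reset_index(drop=True)
    res["rank"] = np.arange(1, len(res) + 1)

    pool = {}
    for fam, frac in fractions.items():
        fam_res = res[res["family"] == fam]
        if fam_res.empty:
            continue
        k = max(1, int(np.floor(frac * len(fam_res))))
        pool[fam] = fam_res.nsmallest(k, "p", keep="first")["feature"].tolist()
    return ScreenResult(res, pool)


def demographics_tests(cohort: pd.DataFrame, group_col: str = "group") -> dict:
    """Group-comparability p-values: age, education (Wilcoxon) and sex (chi2).

    The sex test is a Yates-continuity-corrected chi-squared on the
    2x2 male/female by group contingency table.
    """
    groups = cohort[group_col].unique()
    if len(groups) != 2:
        raise ValueError("need exactly two groups")
    a = cohort[cohort[group_col] == groups[0]]
    b = cohort[cohort[group_col] == groups[1]]
    out = {}
    for col in ("age", "education"):
        p, _, _ = wilcoxon_rank_sum(a[col].to_numpy(float), b[col].to_numpy(float))
        out[col] = p
    tab = pd.crosstab(cohort[group_col], cohort["sex"]).to_numpy()
    if tab.shape != (2, 2) or (tab.sum(axis=1) == 0).any():
        raise ValueError("sex table must be 2x2 with non-empty rows")
    out["sex"] = sex_proportion_test(tab)
    return out


def sex_proportion_test(table_2x2) -> float:
    """Yates-corrected chi-squared p for a 2x2 contingency table."""
    res = sps.chi2_contingency(np.asarray(table_2x2), correction=True)
    return float(res.pvalue)
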