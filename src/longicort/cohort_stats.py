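"""Demographic and behavioral group comparisons.

Welch (default) and pooled two-sample t-tests computable from printed
summary statistics, 2x2 chi-squared with Yates continuity correction
(default; the plain statistic is an option), predictive-mean-matching
imputation of missing RBS-R items, four-factor RBS-R scoring, and
change-score distribution summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import Cohort, N_RBSR_ITEMS


@dataclass
class GroupTestResult:
    statistic: float
    df: float
    p: float
    family: str     # welch-t | pooled-t | chi2-yates | chi2-plain


@dataclass
class RbsrScores:
    """Totals, factor scores and change scores for a scored cohort."""

    total_t1: np.ndarray
    total_t2: np.ndarray
    factors_t1: dict[str, np.ndarray]
    factors_t2: dict[str, np.ndarray]
    delta_total: np.ndarray
    delta_factors: dict[str, np.ndarray]
    factor_map: dict[int, str]


# ---------------------------------------------------------------------------
# Two-sample tests from summary data


def welch_t_from_summary(mean1: float, sd1: float, n1: int,
                         mean2: float, sd2: float, n2: int,
                         pooled: bool = False) -> GroupTestResult:
    """Two-sample t-test from group means, SDs and sizes.

    Welch's unequal-variance form by default; ``pooled=True`` gives the
    classical equal-variance test.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("need at least two observations per group")
    if sd1 < 0 or sd2 < 0 or (sd1 == 0 and sd2 == 0):
        raise ValueError("degenerate variances")
    t, p = stats.ttest_ind_from_stats(mean1, sd1, n1, mean2, sd2, n2,
                                      equal_var=pooled)
    if pooled:
        df = n1 + n2 - 2
        family = "pooled-t"
    else:
        v1, v2 = sd1**2 / n1, sd2**2 / n2
        df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
        family = "welch-t"
    return GroupTestResult(statistic=float(t), df=float(df), p=float(p), family=family)


def chi2_2x2(a: int, b: int, c: int, d: int, continuity: bool = True) -> GroupTestResult:
    """Chi-squared test of a 2x2 table [[a, b], [c, d]].

    Yates continuity correction is applied by default (max(0, |O-E|-0.5)^2
    cell-wise); both margins must be non-degenerate.
    """
    table = np.array([[a, b], [c, d]], dtype=np.int64)
    if np.any(table < 0):
        raise ValueError("counts must be non-negative")
    if np.any(table.sum(axis=0) == 0) or np.any(table.sum(axis=1) == 0):
        raise ValueError("degenerate margin in 2x2 table")
    stat, p, df, _ = stats.chi2_contingency(table, correction=continuity)
    return GroupTestResult(statistic=float(stat), df=float(df), p=float(p),
                           family="chi2-yates" if continuity else "chi2-plain")


# ---------------------------------------------------------------------------
# Predictive mean matching


def pmm_impute(items: np.ndarray, k_donors: int = 5, seed: int = 0,
               max_missing: int | None = None) -> np.ndarray:
    """Single-imputation predictive mean matching on an ordinal item matrix.

    For each missing cell: an OLS prediction of the item from the columns
    observed in that row, fitted on fully complete rows; the donor pool is
    the ``k_donors`` complete rows with the nearest predicted values, and the
    imputed value is drawn uniformly from the donors' observed values.  The
    imputed value therefore always lies in the item's observed support, and
    complete rows pass through untouched.
    """
    items = np.asarray(items, dtype=np.float64)
    out = items.copy()
    missing = np.isnan(items)
    if not missing.any():
        return out
    if max_missing is not None and np.any(missing.sum(axis=1) > max_missing):
        raise ValueError("a row exceeds the missing-item cap")

    complete = ~missing.any(axis=1)
    n_complete = int(complete.sum())
    rng = np.random.default_rng(seed)

    for j in np.flatnonzero(missing.any(axis=0)):
        if n_complete < k_donors:
            raise ValueError(
                f"item {j}: only {n_complete} complete cases for {k_donors} donors")
        for i in np.flatnonzero(missing[:, j]):
            predictors = np.flatnonzero(~missing[i] & (np.arange(items.shape[1]) != j))
            X = np.column_stack([np.ones(n_complete), items[complete][:, predictors]])
            y = items[complete, j]
            beta, *_ = np.linalg.lstsq(X, y, rcond=None)
            pred_complete = X @ beta
            pred_i = float(np.r_[1.0, items[i, predictors]] @ beta)
            order = np.argsort(np.abs(pred_complete - pred_i), kind="stable")
            donors = y[order[:k_donors]]
            out[i, j] = rng.choice(donors)
    return out


# ---------------------------------------------------------------------------
# RBS-R scoring


def _check_factor_map(factor_map: Mapping[int, str], n_items: int) -> list[str]:
    items = set(factor_map)
    expected = set(range(1, n_items + 1))
    if items != expected:
        raise ValueError(
            f"factor map must assign every item 1..{n_items} to exactly one factor; "
            f"missing {sorted(expected - items)}, extra {sorted(items - expected)}")
    return sorted(set(factor_map.values()))


def score_rbsr(items_t1: np.ndarray, items_t2: np.ndarray,
               factor_map: Mapping[int, str]) -> RbsrScores:
    """Totals and factor scores at both timepoints plus T2-T1 change scores.

    Items must be complete (impute first); ``factor_map`` assigns each
    1-based item to exactly one factor.
    """
    items_t1 = np.atleast_2d(np.asarray(items_t1, dtype=np.float64))
    items_t2 = np.atleast_2d(np.asarray(items_t2, dtype=np.float64))
    if items_t1.shape != items_t2.shape:
        raise ValueError("timepoint item matrices differ in shape")
    if np.isnan(items_t1).any() or np.isnan(items_t2).any():
        raise ValueError("items contain missing values; impute before scoring")
    factors = _check_factor_map(factor_map, items_t1.shape[1])

    def factor_scores(items):
        return {f: items[:, [i - 1 for i in factor_map if factor_map[i] == f]].sum(axis=1)
                for f in factors}

    f1 = factor_scores(items_t1)
    f2 = factor_scores(items_t2)
    return RbsrScores(
        total_t1=items_t1.sum(axis=1), total_t2=items_t2.sum(axis=1),
        factors_t1=f1, factors_t2=f2,
        delta_total=items_t2.sum(axis=1) - items_t1.sum(axis=1),
        delta_factors={f: f2[f] - f1[f] for f in factors},
        factor_map=dict(factor_map))


def change_distribution_summary(delta: np.ndarray) -> dict:
    """Fractions decreased / increased / unchanged and extreme changes."""
    delta = np.asarray(delta, dtype=np.float64)
    if delta.size == 0:
        raise ValueError("empty group")
    n = delta.size
    return {
        "fraction_decreased": float(np.sum(delta < 0) / n),
        "fraction_increased": float(np.sum(delta > 0) / n),
        "fraction_unchanged": float(np.sum(delta == 0) / n),
        "max_decrease": float(delta.min()) if np.any(delta < 0) else 0.0,
        "max_increase": float(delta.max()) if np.any(delta > 0) else 0.0,
    }


# ---------------------------------------------------------------------------
# Cohort-level comparison table


def group_comparison_table(cohort: Cohort, factor_map: Mapping[int, str],
                           seed: int = 0, k_donors: int = 5) -> pd.DataFrame:
    """Group means +- SD with test statistics for the standard covariates.

    RBS-R items are PMM-imputed before scoring.  Continuous rows use the
    Welch t-test; categorical rows use Yates-corrected chi-squared.
    """
    frame = cohort.to_frame()
    asd = frame["group"] == "ASD"
    rows = []

    def cont_row(name, values):
        v = np.asarray(values, dtype=np.float64)
        a, t = v[asd], v[~asd]
        res = welch_t_from_summary(a.mean(), a.std(ddof=1), len(a),
                                   t.mean(), t.std(ddof=1), len(t))
        rows.append({"measure": name,
                     "asd": f"{a.mean():.2f} ± {a.std(ddof=1):.2f}",
                     "td": f"{t.mean():.2f} ± {t.std(ddof=1):.2f}",
                     "statistic": res.statistic, "df": res.df, "p": res.p,
                     "test": res.family})

    def cat_row(name, values, level):
        v = np.asarray(values)
        a, b = np.sum((v == level) & asd), np.sum((v != level) & asd)
        c, d = np.sum((v == level) & ~asd), np.sum((v != level) & ~asd)
        res = chi2_2x2(a, b, c, d, continuity=True)
        rows.append({"measure": name, "asd": f"{a}/{b}", "td": f"{c}/{d}",
                     "statistic": res.statistic, "df": res.df, "p": res.p,
                     "test": res.family})

    cont_row("age_t1", frame["age_t1"])
    cont_row("isi", frame["isi"])
    cont_row("fsiq", frame["fsiq"])
    cat_row("sex (male/female)", frame["sex"], "male")
    cat_row("handedness (right/left)", frame["handedness"], "right")

    t1 = pmm_impute(cohort.rbsr_matrix(1), k_donors=k_donors, seed=seed)
    t2 = pmm_impute(cohort.rbsr_matrix(2), k_donors=k_donors, seed=seed + 1)
    scores = score_rbsr(t1, t2, factor_map)
    cont_row("rbsr_total_t1", scores.total_t1)
    cont_row("rbsr_total_t2", scores.total_t2)
    cont_row("rbsr_delta_total", scores.delta_total)
    for f in sorted(scores.factors_t1):
        cont_row(f"rbsr_{f}_t1", scores.factors_t1[f])
        cont_row(f"rbsr_{f}_t2", scores.factors_t2[f])
    return pd.DataFrame(rows)
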