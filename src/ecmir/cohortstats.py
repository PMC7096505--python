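"""Cohort-level statistics.

Group comparison of IR scores (Welch t by default, Mann-Whitney available),
ordinary least squares linking the IR score to the 58-gene mean log2
expression, a clinico-pathological characteristics table with two-sided
Fisher's exact tests per 2×2, and Kaplan-Meier / log-rank survival analysis
supporting the four-curve ECM × grade layout.  Significance convention:
two-sided p < 0.05, no multiple-testing correction.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

logger = logging.getLogger(__name__)


# --------------------------------------------------------------------------
# Group comparison
# --------------------------------------------------------------------------

def _mann_whitney_exact(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """Two-sided exact Mann-Whitney by full enumeration (handles ties)."""
    pooled = np.concatenate([a, b])
    n1 = a.size
    ranks = stats.rankdata(pooled)
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2
    n = pooled.size
    mid = n1 * b.size / 2
    dev_obs = abs(u_obs - mid)
    count = 0
    total = 0
    for comb in itertools.combinations(range(n), n1):
        u = ranks[list(comb)].sum() - n1 * (n1 + 1) / 2
        total += 1
        if abs(u - mid) >= dev_obs - 1e-12:
            count += 1
    return float(u_obs), count / total


def compare_groups(scores: np.ndarray, groups: np.ndarray,
                   test: str = "welch_t") -> tuple[float, float]:
    """Two-sided two-sample comparison of scores between the two groups.

    welch_t: unequal-variance t with Satterthwaite degrees of freedom.
    mann_whitney: exact by enumeration when both groups are small (total
    n < 20), otherwise the normal approximation with tie correction.
    """
    scores = np.asarray(scores, dtype=float)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {len(levels)}")
    a = scores[groups == levels[0]]
    b = scores[groups == levels[1]]
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if test == "welch_t":
        res = stats.ttest_ind(a, b, equal_var=False)
        return float(res.statistic), float(res.pvalue)
    if test == "mann_whitney":
        if a.size + b.size < 20:
            return _mann_whitney_exact(a, b)
        res = stats.mannwhitneyu(a, b, alternative="two-sided",
                                 method="asymptotic")
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


# --------------------------------------------------------------------------
# Linear association (IR score vs gene expression)
# --------------------------------------------------------------------------

@dataclass
class AssociationResult:
    slope: float
    intercept: float
    slope_se: float
    intercept_se: float
    slope_t: float
    intercept_t: float
    slope_p: float
    intercept_p: float
    r_squared: float
    df_resid: int
    orientation: str                # "ir_on_expr" or "expr_on_ir"


def linear_fit(x: np.ndarray, y: np.ndarray,
               orientation: str = "ir_on_expr") -> AssociationResult:
    """OLS with intercept; default orientation regresses IR score on the
    58-gene mean log2 expression (x = expression, y = score).

    The opposite orientation swaps the roles before fitting and is recorded
    in the result.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if orientation == "expr_on_ir":
        x, y = y, x
    elif orientation != "ir_on_expr":
        raise ValueError(f"unknown orientation {orientation!r}")
    if x.size < 3:
        raise ValueError("need at least 3 observations")
    if np.ptp(x) == 0:
        raise ValueError("predictor is constant")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    (b0, b1) = fit.params
    (se0, se1) = fit.bse
    (t0, t1) = fit.tvalues
    (p0, p1) = fit.pvalues
    logger.info("linear_fit (%s): slope=%.5f (SE %.5f, p=%.3g), R²=%.4f",
                orientation, b1, se1, p1, fit.rsquared)
    return AssociationResult(slope=float(b1), intercept=float(b0),
                             slope_se=float(se1), intercept_se=float(se0),
                             slope_t=float(t1), intercept_t=float(t0),
                             slope_p=float(p1), intercept_p=float(p0),
                             r_squared=float(fit.rsquared),
                             df_resid=int(fit.df_resid),
                             orientation=orientation)


# --------------------------------------------------------------------------
# Characteristics table with Fisher's exact tests
# --------------------------------------------------------------------------

CHARACTERISTIC_COLUMNS = ["size_class", "nodal_status", "er_status",
                          "pgr_status", "her2_status", "grade"]


def fisher_exact_2x2(table: np.ndarray) -> float:
    """Two-sided Fisher's exact p by the point-probability method."""
    return float(stats.fisher_exact(np.asarray(table), alternative="two-sided")[1])


def characteristics_table(cohort: pd.DataFrame,
                          characteristics: list[str] | None = None
                          ) -> pd.DataFrame:
    """Counts and within-group percentages per category level, with Fisher p.

    Percentages are computed within each ECM column over non-missing rows and
    rounded to integer percent.  Characteristics with all-missing values are
    omitted with a warning.  The Fisher p (two-level characteristics only) is
    attached to every level row of its characteristic.
    """
    if characteristics is None:
        characteristics = [c for c in CHARACTERISTIC_COLUMNS
                           if c in cohort.columns]
    if "ecm_class" not in cohort.columns:
        raise ValueError("cohort table has no ecm_class column")
    groups = ["ECM3", "non-ECM3"]
    rows = []
    for char in characteristics:
        sub = cohort[["ecm_class", char]].dropna()
        if sub.empty:
            logger.warning("characteristics_table: '%s' all missing; omitted",
                           char)
            continue
        levels = sorted(sub[char].unique())
        counts = {g: sub[sub.ecm_class == g][char].value_counts()
                  for g in groups}
        totals = {g: int(sum(counts[g])) for g in groups}
        p = np.nan
        if len(levels) == 2:
            tab = [[int(counts[g].get(l, 0)) for l in levels] for g in groups]
            p = fisher_exact_2x2(np.array(tab))
        for l in levels:
            row = {"characteristic": char, "level": l, "fisher_p": p}
            for g in groups:
                c = int(counts[g].get(l, 0))
                row[f"{g}_count"] = c
                row[f"{g}_pct"] = round(100 * c / totals[g]) if totals[g] else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Survival: Kaplan-Meier and log-rank
# --------------------------------------------------------------------------

@dataclass
class SurvivalFit:
    event_times: np.ndarray          # distinct times in the estimator timeline
    survival: np.ndarray             # KM estimate at those times
    at_risk: np.ndarray              # subjects at risk just before each time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times: np.ndarray, events: np.ndarray) -> SurvivalFit:
    """Product-limit survival estimate for one group.

    At tied times events are processed before censorings (subjects censored
    at t remain at risk for events at t).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    if np.any(times < 0):
        raise ValueError("survival times must be non-negative")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    timeline = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=float)
    # drop the timeline origin row when it is a synthetic t=0 entry
    return SurvivalFit(event_times=timeline, survival=surv, at_risk=at_risk)


def logrank(times: np.ndarray, events: np.ndarray,
            groups: np.ndarray) -> tuple[float, int, float]:
    """k-sample log-rank test; returns (χ², df, p)."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    levels = pd.unique(groups)
    if len(levels) < 2:
        raise ValueError("log-rank needs at least two groups")
    if events.sum() < 1:
        raise ValueError("log-rank needs at least one event")
    res = multivariate_logrank_test(times, groups, events)
    return float(res.test_statistic), len(levels) - 1, float(res.p_value)


def survival_by_ecm_and_grade(cohort: pd.DataFrame,
                              ecm_column: str = "ecm_class"
                              ) -> dict:
    """Fig-5-style four-group survival: ECM3/non-ECM3 × grade I-II/III.

    Returns per-group KM fits plus the overall 4-group log-rank test and the
    2-group test restricted to grade III tumors (the prognostic interaction).
    """
    df = cohort.dropna(subset=[ecm_column, "grade", "survival_months", "event"])
    label = df[ecm_column].astype(str) + " G" + df["grade"].astype(str)
    fits = {name: km_estimate(sub["survival_months"].to_numpy(),
                              sub["event"].to_numpy())
            for name, sub in df.groupby(label)}
    chi2, dof, p = logrank(df["survival_months"].to_numpy(),
                           df["event"].to_numpy(), label.to_numpy())
    g3 = df[df["grade"] == "III"]
    out = {"km_fits": fits, "logrank_chi2": chi2, "logrank_df": dof,
           "logrank_p": p}
    if g3[ecm_column].nunique() == 2 and g3["event"].sum() >= 1:
        c2, d2, p2 = logrank(g3["survival_months"].to_numpy(),
                             g3["event"].to_numpy(),
                             g3[ecm_column].to_numpy())
        out.update({"gradeIII_logrank_chi2": c2, "gradeIII_logrank_p": p2})
    return out
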