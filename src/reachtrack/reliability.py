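"""Test–retest reliability: two-way ANOVA, ICC, Pearson LCC, age trends.

Reliability of each metric is assessed from the subjects x trials matrix of
per-subject means (subtasks pre-averaged unless stratified):

* ICC(2,k) — two-way agreement form for the average of k = 2 trials,
  ``(MSR - MSE) / (MSR + (MSC - MSE)/n)`` from a two-way ANOVA without
  replication, with the F-based Shrout–Fleiss/McGraw–Wong 95% CI.
  ICC(3,k) = (MSR - MSE)/MSR (consistency form) is reported alongside.
* LCC — Pearson r between the trial-1 and trial-2 columns, 95% CI by the
  Fisher z-transform.
* Age trends — ordinary least-squares regression of per-subject metric
  means on age, two-sided p for a nonzero slope.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats

from .metrics import METRIC_NAMES

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SubjectTrialMatrix:
    """Per-subject per-trial values of one metric (complete cases only)."""

    metric: str
    values: np.ndarray            # shape (n_subjects, k)
    ages: np.ndarray              # shape (n_subjects,)
    participant_ids: Tuple[str, ...] = ()

    def __post_init__(self) -> None:
        v = np.asarray(self.values, float)
        if v.ndim != 2 or v.shape[0] < 3 or v.shape[1] < 2:
            raise ValueError("need a complete n>=3 by k>=2 matrix")
        if np.isnan(v).any():
            raise ValueError("matrix contains missing cells; drop those "
                             "subjects upstream (listwise)")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def k(self) -> int:
        return self.values.shape[1]


@dataclass(frozen=True)
class ReliabilityResult:
    metric: str
    icc: float
    icc_ci95: Tuple[float, float]
    icc3k: float
    icc3k_ci95: Tuple[float, float]
    lcc: float
    lcc_ci95: Tuple[float, float]
    n: int
    k: int = 2


@dataclass(frozen=True)
class RegressionResult:
    metric: str
    subtask: str
    slope: float
    intercept: float
    r: float
    p_value: float
    stderr: float
    n: int


def subject_trial_matrix(table: pd.DataFrame, metric: str,
                         subtask: Optional[str] = None) -> SubjectTrialMatrix:
    """Build the subjects x trials matrix from a metric table.

    Values are averaged over the six subtasks per subject and trial
    (pre-averaging), or restricted to one subtask when ``subtask`` is
    given.  Subjects with any missing cell are dropped listwise (logged).
    """
    if metric not in METRIC_NAMES:
        raise KeyError(f"unknown metric {metric!r}")
    df = table if subtask is None else table[table["subtask"] == subtask]
    wide = (df.groupby(["participant_id", "trial"])[metric].mean()
            .unstack("trial"))
    ages = table.groupby("participant_id")["age"].first()
    complete = wide.dropna()
    dropped = len(wide) - len(complete)
    if dropped:
        logger.info("dropping %d subject(s) with missing %s values",
                    dropped, metric)
    return SubjectTrialMatrix(
        metric=metric, values=complete.to_numpy(float),
        ages=ages.loc[complete.index].to_numpy(float),
        participant_ids=tuple(complete.index))


def anova_two_way_no_rep(matrix: SubjectTrialMatrix
                         ) -> Tuple[float, float, float]:
    """Mean squares (MSR, MSC, MSE) of the two-way ANOVA without
    replication: rows = subjects, columns = trials."""
    v = matrix.values
    n, k = v.shape
    grand = v.mean()
    ss_rows = k * np.sum((v.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((v.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((v - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return float(msr), float(msc), float(max(mse, 0.0))


def _spearman_brown(r1: float, k: int) -> float:
    denom = 1.0 + (k - 1) * r1
    if denom <= 1e-12:          # floor: r1 at/below -1/(k-1)
        return -1.0
    return k * r1 / denom


def icc_2k(matrix: SubjectTrialMatrix, alpha: float = 0.05
           ) -> ReliabilityResult:
    """ICC(2,k) and ICC(3,k) with 95% confidence intervals.

    The agreement CI follows the F-based single-rater procedure
    (Shrout & Fleiss 1979; McGraw & Wong 1996), Spearman–Brown scaled to
    average measures; the consistency CI uses the exact F pivot.
    """
    msr, msc, mse = anova_two_way_no_rep(matrix)
    n, k = matrix.n, matrix.k
    if msr <= 0:
        logger.warning("no between-subject variance; ICC reported as 0")
        nan = float("nan")
        return ReliabilityResult(matrix.metric, 0.0, (0.0, 0.0), 0.0,
                                 (0.0, 0.0), nan, (nan, nan), n, k)
    icc2k = (msr - mse) / (msr + (msc - mse) / n)

    # single-measure agreement ICC and its F-based CI
    icc2 = (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)
    if icc2 >= 1.0:             # degenerate: perfect agreement
        lcc_r, lcc_ci = _lcc_parts(matrix, alpha)
        return ReliabilityResult(metric=matrix.metric, icc=1.0,
                                 icc_ci95=(1.0, 1.0), icc3k=1.0,
                                 icc3k_ci95=(1.0, 1.0), lcc=lcc_r,
                                 lcc_ci95=lcc_ci, n=n, k=k)
    denom = n * (1.0 - icc2)
    a = k * icc2 / denom
    b = 1.0 + k * icc2 * (n - 1) / denom
    with np.errstate(invalid="ignore", divide="ignore"):
        dof = ((a * msc + b * mse) ** 2
               / ((a * msc) ** 2 / (k - 1)
                  + (b * mse) ** 2 / ((n - 1) * (k - 1))))
    dof = float(max(dof, 1.0)) if np.isfinite(dof) else float((n - 1) * (k - 1))
    f1 = stats.f.ppf(1 - alpha / 2, n - 1, dof)
    f2 = stats.f.ppf(1 - alpha / 2, dof, n - 1)
    lo1 = (n * (msr - f1 * mse)
           / (f1 * (k * msc + (k * n - k - n) * mse) + n * msr))
    hi1 = (n * (f2 * msr - mse)
           / (k * msc + (k * n - k - n) * mse + n * f2 * msr))
    lo = _spearman_brown(float(np.clip(lo1, -1.0, 1.0)), k)
    hi = _spearman_brown(float(np.clip(hi1, -1.0, 1.0)), k)
    lo, hi = min(lo, icc2k), max(hi, icc2k)

    # consistency form and its exact F CI
    icc3k = (msr - mse) / msr
    if mse > 0:
        fobs = msr / mse
        fl = stats.f.ppf(1 - alpha / 2, n - 1, (n - 1) * (k - 1))
        fu = stats.f.ppf(1 - alpha / 2, (n - 1) * (k - 1), n - 1)
        ci3 = (float(1 - fl / fobs), float(1 - 1 / (fobs * fu)))
    else:
        ci3 = (icc3k, icc3k)

    lcc_r, lcc_ci = _lcc_parts(matrix, alpha)
    return ReliabilityResult(metric=matrix.metric, icc=float(icc2k),
                             icc_ci95=(lo, hi), icc3k=float(icc3k),
                             icc3k_ci95=ci3, lcc=lcc_r, lcc_ci95=lcc_ci,
                             n=n, k=k)


def fisher_ci(r: float, n: int, alpha: float = 0.05) -> Tuple[float, float]:
    """Fisher z-transform confidence interval for a Pearson correlation."""
    if n < 4:
        raise ValueError("need n >= 4 for a Fisher z interval")
    if abs(r) >= 1.0:          # degenerate: perfect correlation
        return float(r), float(r)
    z = np.arctanh(r)
    se = 1.0 / np.sqrt(n - 3)
    zc = stats.norm.ppf(1 - alpha / 2)
    return float(np.tanh(z - zc * se)), float(np.tanh(z + zc * se))


def _lcc_parts(matrix: SubjectTrialMatrix, alpha: float = 0.05
               ) -> Tuple[float, Tuple[float, float]]:
    t1, t2 = matrix.values[:, 0], matrix.values[:, 1]
    if np.std(t1) == 0 or np.std(t2) == 0:
        raise ValueError("zero variance in a trial column; LCC undefined")
    r = float(stats.pearsonr(t1, t2).statistic)
    return r, fisher_ci(r, matrix.n, alpha)


def lcc(matrix: SubjectTrialMatrix, alpha: float = 0.05) -> ReliabilityResult:
    """Pearson correlation between the two trial columns, Fisher z 95% CI.

    The ICC fields of the returned result are NaN; use :func:`icc_2k` for
    the full reliability summary.
    """
    r, ci = _lcc_parts(matrix, alpha)
    nan = float("nan")
    return ReliabilityResult(metric=matrix.metric, icc=nan, icc_ci95=(nan, nan),
                             icc3k=nan, icc3k_ci95=(nan, nan),
                             lcc=r, lcc_ci95=ci, n=matrix.n, k=matrix.k)


def age_regression(values: np.ndarray, ages: np.ndarray, metric: str = "",
                   subtask: str = "all") -> RegressionResult:
    """OLS regression of per-subject metric means on age."""
    values = np.asarray(values, float)
    ages = np.asarray(ages, float)
    ok = ~(np.isnan(values) | np.isnan(ages))
    values, ages = values[ok], ages[ok]
    if len(values) < 3:
        raise ValueError("need at least 3 subjects")
    if np.std(ages) == 0:
        raise ValueError("ages are constant; age slope is unidentifiable")
    fit = stats.linregress(ages, values)
    return RegressionResult(metric=metric, subtask=subtask,
                            slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r=float(fit.rvalue), p_value=float(fit.pvalue),
                            stderr=float(fit.stderr), n=len(values))


def trial_vs_trial(matrix: SubjectTrialMatrix) -> RegressionResult:
    """Trial-2-on-trial-1 regression line across subjects (the per-metric
    consistency panel)."""
    if matrix.n < 3:
        raise ValueError("need at least 3 subjects")
    t1, t2 = matrix.values[:, 0], matrix.values[:, 1]
    if np.std(t1) == 0:
        raise ValueError("trial 1 has zero variance")
    fit = stats.linregress(t1, t2)
    return RegressionResult(metric=matrix.metric, subtask="all",
                            slope=float(fit.slope),
                            intercept=float(fit.intercept),
                            r=float(fit.rvalue), p_value=float(fit.pvalue),
                            stderr=float(fit.stderr), n=matrix.n)


def reliability_table(table: pd.DataFrame,
                      metrics: Tuple[str, ...] = METRIC_NAMES
                      ) -> List[ReliabilityResult]:
    """ICC/LCC summary for each metric of a two-trial metric table."""
    return [icc_2k(subject_trial_matrix(table, m)) for m in metrics]


def age_trend_table(table: pd.DataFrame,
                    metrics: Tuple[str, ...] = METRIC_NAMES,
                    per_subtask: bool = True) -> List[RegressionResult]:
    """Age regressions of trial-averaged metric values, per subtask."""
    out: List[RegressionResult] = []
    subtasks = (sorted(table["subtask"].unique(), key=str)
                if per_subtask else [None])
    for metric in metrics:
        for sub in subtasks:
            df = table if sub is None else table[table["subtask"] == sub]
            per_subj = df.groupby("participant_id").agg(
                value=(metric, "mean"), age=("age", "first"))
            out.append(age_regression(per_subj["value"].to_numpy(),
                                      per_subj["age"].to_numpy(),
                                      metric=metric,
                                      subtask=sub if sub else "all"))
    return out
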