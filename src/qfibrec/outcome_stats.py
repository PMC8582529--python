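"""Outcome evaluation: ROC, confusion metrics, rank tests, KM, Cox, summaries.

This stage judges a risk index (the combined index, or any competing marker
such as AFP) against recurrence and survival outcomes: discrimination via
ROC/AUC, a cutoff confusion matrix, group comparison of indices by the
two-tailed Wilcoxon rank-sum test, disease-free Kaplan-Meier curves compared
by the log-rank test, univariate and multivariate Cox proportional-hazards
models (Efron tie handling, Wald confidence intervals), Pearson correlation,
and per-stratum event summaries in the style of a clinical baseline table.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_curve as _sk_roc_curve

from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test, multivariate_logrank_test
from lifelines.utils import ConvergenceWarning


# ---------------------------------------------------------------------------
# ROC / confusion
# ---------------------------------------------------------------------------


@dataclass
class ROCCurve:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    chosen_cutoff: float  # maximizes Youden's J on this curve


def roc_auc(scores, labels) -> ROCCurve:
    """ROC curve with AUC by tie-corrected pair counting (higher score = positive).

    The AUC equals the Mann-Whitney statistic U/(n1*n0) with ties counted as
    half-concordant, which is also the trapezoidal area under the curve.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValueError("roc_auc requires both classes present")
    ranks = stats.rankdata(scores)
    auc = (ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0)
    fpr, tpr, thr = _sk_roc_curve(labels, scores)
    j = tpr - fpr
    chosen = float(thr[int(np.argmax(j))])
    return ROCCurve(fpr=fpr, tpr=tpr, thresholds=thr, auc=float(auc), chosen_cutoff=chosen)


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def fpr(self) -> float:
        return 1.0 - self.specificity

    @property
    def fnr(self) -> float:
        return 1.0 - self.sensitivity

    def as_percent(self) -> dict[str, float]:
        """Rates as percentages rounded to 1 decimal, report style."""
        return {
            "sensitivity": round(100 * self.sensitivity, 1),
            "specificity": round(100 * self.specificity, 1),
            "fpr": round(100 * self.fpr, 1),
            "fnr": round(100 * self.fnr, 1),
        }


def confusion_metrics(predicted, truth) -> ConfusionMetrics:
    """Confusion counts of binary risk calls against binary truth."""
    predicted = np.asarray(predicted).astype(int)
    truth = np.asarray(truth).astype(int)
    if predicted.shape != truth.shape:
        raise ValueError("predicted and truth lengths differ")
    return ConfusionMetrics(
        tp=int(((predicted == 1) & (truth == 1)).sum()),
        fp=int(((predicted == 1) & (truth == 0)).sum()),
        fn=int(((predicted == 0) & (truth == 1)).sum()),
        tn=int(((predicted == 0) & (truth == 0)).sum()),
    )


# ---------------------------------------------------------------------------
# rank / correlation tests
# ---------------------------------------------------------------------------


def wilcoxon_rank_sum(x, y) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) test; returns (U, p).

    Exact enumeration when min(n, m) <= 8 with no ties; otherwise the normal
    approximation with tie and continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    method = "exact" if (min(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.statistic), float(res.pvalue)


def pearson_corr(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with t-based two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y) or len(x) < 3:
        raise ValueError("pearson_corr requires paired samples with n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("pearson_corr requires nonzero variance in both inputs")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# ---------------------------------------------------------------------------
# survival
# ---------------------------------------------------------------------------


@dataclass
class SurvivalCurve:
    group: str
    times: np.ndarray
    at_risk: np.ndarray
    survival: np.ndarray  # step survival probabilities at `times`


def km_logrank(
    times, events, groups
) -> tuple[dict[str, SurvivalCurve], float, float]:
    """Kaplan-Meier curves per group plus the log-rank test.

    Returns (curves, chi-square, p).  Two groups give the classical 1-df
    log-rank; more groups use the k-sample generalization.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    groups = np.asarray(groups)
    if (times < 0).any():
        raise ValueError("times must be nonnegative")
    labels = pd.unique(groups)
    if len(labels) < 2:
        raise ValueError("km_logrank requires at least two groups")

    curves = {}
    for lab in labels:
        m = groups == lab
        if not m.any():
            raise ValueError(f"group {lab!r} has no subjects")
        kmf = KaplanMeierFitter()
        kmf.fit(times[m], events[m], label=str(lab))
        tab = kmf.event_table
        curves[str(lab)] = SurvivalCurve(
            group=str(lab),
            times=tab.index.to_numpy(dtype=float),
            at_risk=tab["at_risk"].to_numpy(dtype=float),
            survival=kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float),
        )

    if len(labels) == 2:
        m0 = groups == labels[0]
        res = logrank_test(times[m0], times[~m0], events[m0], events[~m0])
    else:
        res = multivariate_logrank_test(times, groups, events)
    return curves, float(res.test_statistic), float(res.p_value)


@dataclass
class CoxResult:
    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    model_type: str  # 'univariate' | 'multivariate'
    converged: bool = True


def cox_ph(
    df: pd.DataFrame,
    covariates: list[str],
    duration_col: str,
    event_col: str,
    mode: str = "multivariate",
) -> list[CoxResult]:
    """Cox proportional-hazards fits (Efron ties, Wald 95% CIs).

    ``univariate`` fits one covariate at a time; ``multivariate`` fits all
    jointly.  A monotone partial likelihood (perfect separation) is flagged
    with ``converged=False`` and NaN estimates rather than a spurious number.
    """
    if mode not in ("univariate", "multivariate"):
        raise ValueError("mode must be 'univariate' or 'multivariate'")
    if int(df[event_col].sum()) < 2:
        raise ValueError("cox_ph requires at least 2 events")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} has zero variance")

    groups = [[c] for c in covariates] if mode == "univariate" else [covariates]
    results: list[CoxResult] = []
    for cols in groups:
        data = df[cols + [duration_col, event_col]]
        cph = CoxPHFitter()
        flagged = False
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                cph.fit(
                    data,
                    duration_col=duration_col,
                    event_col=event_col,
                    fit_options={"precision": 1e-9},
                )
            except ConvergenceError:
                flagged = True
            else:
                flagged = any(issubclass(w.category, ConvergenceWarning) for w in caught)
        for c in cols:
            if flagged:
                results.append(
                    CoxResult(c, float("nan"), float("nan"), float("nan"),
                              float("nan"), mode, converged=False)
                )
                continue
            s = cph.summary.loc[c]
            results.append(
                CoxResult(
                    covariate=c,
                    hazard_ratio=float(s["exp(coef)"]),
                    ci_low=float(s["exp(coef) lower 95%"]),
                    ci_high=float(s["exp(coef) upper 95%"]),
                    p_value=float(s["p"]),
                    model_type=mode,
                )
            )
    return results


def cox_results_frame(results: list[CoxResult]) -> pd.DataFrame:
    """Report table: HRs to 3 decimals, CI bounds to 3 decimals."""
    rows = []
    for r in results:
        rows.append(
            {
                "covariate": r.covariate,
                "HR": round(r.hazard_ratio, 3) if np.isfinite(r.hazard_ratio) else np.nan,
                "CI95_low": round(r.ci_low, 3) if np.isfinite(r.ci_low) else np.nan,
                "CI95_high": round(r.ci_high, 3) if np.isfinite(r.ci_high) else np.nan,
                "p": r.p_value,
                "model": r.model_type,
                "converged": r.converged,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# contingency summaries
# ---------------------------------------------------------------------------


def stratum_summary(df: pd.DataFrame, stratifier, event_col: str) -> pd.DataFrame:
    """Per-stratum patient count, event count and percent (1 decimal).

    ``stratifier`` is a column name or an aligned Series; strata with zero
    patients report percent as missing.
    """
    strat = df[stratifier] if isinstance(stratifier, str) else pd.Series(stratifier, index=df.index)
    if strat.isna().any():
        raise ValueError("stratifier must be defined for all records")
    out = (
        df.groupby(strat, observed=False)[event_col]
        .agg(n_patients="count", n_events="sum")
        .reset_index()
        .rename(columns={strat.name if strat.name else "index": "stratum"})
    )
    out.columns = ["stratum", "n_patients", "n_events"]
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = np.where(
            out["n_patients"] > 0,
            np.round(100.0 * out["n_events"] / out["n_patients"].replace(0, np.nan), 1),
            np.nan,
        )
    out["percent"] = pct
    return out
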