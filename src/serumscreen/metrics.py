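"""Diagnostic evaluation of screening markers and risk scores.

Empirical ROC curves with DeLong confidence intervals, Youden-index
operating points, confusion-table metrics (sensitivity, specificity,
PPV, NPV, likelihood ratios), detection rate at a fixed false-positive
rate, and multivariate logistic regression with Wald intervals on the
odds ratios.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps
from statsmodels.tools.sm_exceptions import (
    PerfectSeparationError,
    PerfectSeparationWarning,
)

HIGHER = "higher_is_positive"
LOWER = "lower_is_positive"


@dataclass
class ROCResult:
    """Empirical ROC curve with DeLong AUC inference.

    ``points`` has one row per distinct cutoff (plus the trivial
    all-negative point) with columns ``cutoff, fpr, tpr``; cutoffs follow
    the midpoint-between-distinct-scores convention and are on the
    original score scale ('positive' means beyond the cutoff in the
    stated direction).
    """

    points: pd.DataFrame
    auc: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    direction: str
    n_case: int
    n_ctrl: int


@dataclass
class CutoffMetrics:
    """Confusion-table metrics at one operating point."""

    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    plr: float
    nlr: float
    counts: dict[str, int] = field(default_factory=dict)
    direction: str = HIGHER

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


def _orient(scores: np.ndarray, labels: np.ndarray, direction: str):
    """Map scores so that larger always means 'more case-like'."""
    cases = scores[labels == 1]
    ctrls = scores[labels == 0]
    if direction == "auto":
        direction = HIGHER if cases.mean() >= ctrls.mean() else LOWER
    if direction not in (HIGHER, LOWER):
        raise ValueError(f"unknown direction {direction!r}")
    sign = 1.0 if direction == HIGHER else -1.0
    return sign * scores, direction, sign


def _delong(cases: np.ndarray, ctrls: np.ndarray) -> tuple[float, float]:
    """AUC and its DeLong variance via midrank placements."""
    m, n = cases.size, ctrls.size
    combined = np.concatenate([cases, ctrls])
    rk = sps.rankdata(combined)
    rk_cases = sps.rankdata(cases)
    rk_ctrls = sps.rankdata(ctrls)
    v10 = (rk[:m] - rk_cases) / n  # placement of each case among controls
    v01 = 1.0 - (rk[m:] - rk_ctrls) / m
    auc = float(v10.mean())
    if m > 1 and n > 1:
        var = v10.var(ddof=1) / m + v01.var(ddof=1) / n
    else:
        var = np.nan
    return auc, float(var)


def roc_curve(
    scores,
    labels,
    direction: str = "auto",
    alpha: float = 0.05,
) -> ROCResult:
    """Empirical ROC over all distinct cutoffs, with DeLong CI for the AUC.

    ``labels`` are 1 for cases (affected) and 0 for controls.  The AUC is
    the trapezoidal area, identical to the Mann-Whitney probability
    P(case > control) + 0.5 P(tie); the p-value tests AUC = 0.5 by the
    DeLong normal statistic.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    s, direction, sign = _orient(scores, labels, direction)
    cases = s[labels == 1]
    ctrls = s[labels == 0]
    m, n = cases.size, ctrls.size

    u = np.unique(s)[::-1]  # distinct oriented scores, descending
    # Positives at step i are subjects with oriented score >= u[i]; the
    # reported cutoff is the midpoint between u[i] and the next lower
    # distinct score (one unit beyond the extremes).
    cases_sorted = np.sort(-cases)  # ascending in -score for searchsorted
    ctrls_sorted = np.sort(-ctrls)
    tpr = np.concatenate(
        [[0.0], np.searchsorted(cases_sorted, -u, side="right") / m]
    )
    fpr = np.concatenate(
        [[0.0], np.searchsorted(ctrls_sorted, -u, side="right") / n]
    )
    mids = np.empty(u.size + 1)
    mids[0] = u[0] + 1.0
    mids[1:-1] = (u[:-1] + u[1:]) / 2.0
    mids[-1] = u[-1] - 1.0
    cutoffs = sign * mids

    auc = float(np.trapezoid(tpr, fpr))
    auc_d, var = _delong(cases, ctrls)
    se = float(np.sqrt(var)) if np.isfinite(var) else np.nan
    z = sps.norm.ppf(1 - alpha / 2)
    if np.isfinite(se) and se > 0:
        ci_low = max(0.0, auc - z * se)
        ci_high = min(1.0, auc + z * se)
        p = 2 * sps.norm.sf(abs(auc - 0.5) / se)
    else:
        ci_low, ci_high = auc, auc
        p = 0.0 if auc != 0.5 else 1.0
    points = pd.DataFrame({"cutoff": cutoffs, "fpr": fpr, "tpr": tpr})
    return ROCResult(
        points=points,
        auc=auc,
        se=se,
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        p_value=float(p),
        direction=direction,
        n_case=m,
        n_ctrl=n,
    )


def youden_cutoff(roc: ROCResult) -> CutoffMetrics:
    """Operating point maximizing Youden's J = sensitivity + specificity - 1.

    Ties in J are broken toward the higher sensitivity.
    """
    tpr = roc.points["tpr"].to_numpy()
    fpr = roc.points["fpr"].to_numpy()
    j = tpr - fpr
    best = np.lexsort((tpr, j))[-1]  # max J, then max sensitivity
    sens = float(tpr[best])
    spec = float(1.0 - fpr[best])
    tp = int(round(sens * roc.n_case))
    fp = int(round(fpr[best] * roc.n_ctrl))
    counts = {
        "tp": tp,
        "fp": fp,
        "fn": roc.n_case - tp,
        "tn": roc.n_ctrl - fp,
    }
    return _metrics_from_counts(
        counts, float(roc.points["cutoff"].iloc[best]), roc.direction
    )


def _metrics_from_counts(
    counts: dict[str, int], cutoff: float, direction: str = HIGHER
) -> CutoffMetrics:
    tp, fp, fn, tn = counts["tp"], counts["fp"], counts["fn"], counts["tn"]
    n_case, n_ctrl = tp + fn, tn + fp
    sens = tp / n_case
    spec = tn / n_ctrl
    ppv = tp / (tp + fp) if tp + fp else np.nan
    npv = tn / (tn + fn) if tn + fn else np.nan
    fpr = fp / n_ctrl
    plr = sens / fpr if fpr > 0 else np.inf
    nlr = (1.0 - sens) / spec if spec > 0 else np.inf
    return CutoffMetrics(
        cutoff=cutoff,
        sensitivity=sens,
        specificity=spec,
        ppv=ppv,
        npv=npv,
        plr=plr,
        nlr=nlr,
        counts=counts,
        direction=direction,
    )


def metrics_from_rates(
    sensitivity: float,
    specificity: float,
    n_case: int,
    n_ctrl: int,
    cutoff: float = np.nan,
) -> CutoffMetrics:
    """Predictive values and likelihood ratios from reported rates.

    Rates are first converted to integer confusion counts
    (``tp = round(sens * n_case)`` etc.), then all metrics are recomputed
    from the counts, which is how published screening tables are derived.
    """
    if not (0.0 <= sensitivity <= 1.0 and 0.0 <= specificity <= 1.0):
        raise ValueError("sensitivity and specificity must be in [0, 1]")
    if n_case <= 0 or n_ctrl <= 0:
        raise ValueError("group sizes must be positive")
    tp = int(round(sensitivity * n_case))
    tn = int(round(specificity * n_ctrl))
    counts = {"tp": tp, "fn": n_case - tp, "tn": tn, "fp": n_ctrl - tn}
    return _metrics_from_counts(counts, cutoff)


def threshold_for_fpr(control_scores, target_fpr: float) -> float:
    """Cutoff whose exceedance rate among controls is <= target_fpr.

    Scores are oriented 'higher is positive'.  The cutoff sits at the
    midpoint between the k-th and (k+1)-th largest control scores with
    ``k = floor(target_fpr * n)``, so the achieved FPR is the largest
    attainable step value not exceeding the target.
    """
    s = np.sort(np.asarray(control_scores, dtype=float))[::-1]
    n = s.size
    if n == 0:
        raise ValueError("no control scores")
    if not 0.0 < target_fpr < 1.0:
        raise ValueError("target_fpr must be in (0, 1)")
    k = int(np.floor(target_fpr * n))
    if k < 1:
        raise ValueError(
            f"target_fpr {target_fpr} unreachable with {n} controls"
        )
    return float((s[k - 1] + s[k]) / 2.0)


def detection_rate_at_fpr(
    scores,
    labels,
    target_fpr: float = 0.05,
    direction: str = "auto",
) -> tuple[float, float]:
    """Fraction of cases flagged when the cutoff fixes the control FPR.

    Returns ``(detection_rate, cutoff)``; the cutoff is on the original
    score scale and 'positive' means beyond it in the chosen direction.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    if set(np.unique(labels)) != {0, 1}:
        raise ValueError("labels must contain both classes (0 and 1)")
    s, direction, sign = _orient(scores, labels, direction)
    cutoff = threshold_for_fpr(s[labels == 0], target_fpr)
    rate = float(np.mean(s[labels == 1] > cutoff))
    return rate, sign * cutoff


@dataclass
class LogisticFit:
    """Multivariate logistic regression with Wald odds-ratio intervals."""

    table: pd.DataFrame  # coef, exp_b, ci_low, ci_high, p_value per covariate
    converged: bool
    n_iterations: int
    separation: bool = False


def logistic_fit(
    X,
    y,
    add_intercept: bool = True,
    maxiter: int = 100,
    tol: float = 1e-8,
) -> LogisticFit:
    """Maximum-likelihood logistic fit (Newton/IRLS) with Wald CIs.

    ``X`` is a DataFrame (or array) of covariates, ``y`` a binary
    outcome.  Perfect separation is flagged and the fit reported as not
    converged rather than raised.
    """
    Xd = pd.DataFrame(X).copy()
    Xd.columns = [str(c) for c in Xd.columns]
    y = np.asarray(y).astype(float)
    if len(Xd) <= Xd.shape[1] + int(add_intercept):
        raise ValueError("need more observations than covariates")
    exog = sm.add_constant(Xd, has_constant="raise") if add_intercept else Xd
    names = list(exog.columns)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", PerfectSeparationWarning)
            res = sm.Logit(y, exog).fit(
                disp=0, maxiter=maxiter, method="newton", tol=tol
            )
    except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
        nan = np.full(len(names), np.nan)
        table = pd.DataFrame(
            {"coef": nan, "exp_b": nan, "ci_low": nan, "ci_high": nan,
             "p_value": nan},
            index=names,
        )
        return LogisticFit(table=table, converged=False,
                           n_iterations=maxiter, separation=True)
    ci = np.exp(res.conf_int())
    table = pd.DataFrame(
        {
            "coef": res.params,
            "exp_b": np.exp(res.params),
            "ci_low": ci.iloc[:, 0],
            "ci_high": ci.iloc[:, 1],
            "p_value": res.pvalues,
        },
        index=names,
    )
    converged = bool(res.mle_retvals.get("converged", False))
    # huge coefficients with a 'converged' flag still indicate separation
    separation = bool(np.any(np.abs(res.params) > 30))
    return LogisticFit(
        table=table,
        converged=converged and not separation,
        n_iterations=int(res.mle_retvals.get("iterations", maxiter)),
        separation=separation,
    )
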