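"""Cohort-level statistics, implemented from first principles.

This layer provides the nonparametric and categorical tests, ROC analysis
with a highest-sensitivity-plus-specificity cutoff, univariate logistic
odds ratios, and Kaplan-Meier / log-rank survival comparison used to relate
f-wave amplitude to long-term ablation outcome.  Established library
implementations (scipy, statsmodels, lifelines) serve only as independent
cross-checks in the test suite; the estimators here are self-contained.

Conventions: p-values are two-sided; SUCCESS (sinus-rhythm maintenance) is
the positive class throughout; odds ratios are reported per stated
predictor increment (0.01 mV for amplitude predictors, one percentage
point for relative-change predictors), since a per-1-mV step would be
meaningless for amplitudes of order 0.04 mV.  No multiple-testing
correction is applied by default; per-lead p-values are reported raw with
an optional Benjamini-Hochberg column.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from itertools import combinations
from math import comb, erf, sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst

from .io import CohortTable, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "mann_whitney", "fisher_exact_2x2", "chi2_test",
    "RocResult", "roc_analysis",
    "LogisticFit", "logistic_fit_univariate",
    "KmCurve", "km_estimate", "logrank",
    "compare_groups", "predictor_analysis", "benjamini_hochberg",
]


def _norm_sf(z: float) -> float:
    return 0.5 * (1.0 - erf(z / sqrt(2.0)))


# ---------------------------------------------------------------------------
# Mann-Whitney U
# ---------------------------------------------------------------------------

def _midranks(pooled: np.ndarray) -> np.ndarray:
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(len(pooled))
    sorted_vals = pooled[order]
    i = 0
    while i < len(pooled):
        j = i
        while j + 1 < len(pooled) and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i:j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def mann_whitney(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U test.

    Uses midranks for ties.  The p-value is exact (full enumeration of the
    null permutation distribution of U) when n+m <= 16 and the pooled data
    are tie-free; otherwise the normal approximation with tie and
    continuity corrections is used.

    Returns ``(U, p)`` where U counts pairs in which x exceeds y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) == 0 or len(y) == 0:
        raise ValidationError("mann_whitney requires two non-empty samples")
    n, m = len(x), len(y)
    pooled = np.concatenate([x, y])
    ranks = _midranks(pooled)
    u = float(np.sum(ranks[:n]) - n * (n + 1) / 2)
    has_ties = len(np.unique(pooled)) < n + m
    mu = n * m / 2.0
    if n + m <= 16 and not has_ties:
        # exact two-sided p: share of rank assignments at least as far from
        # the null mean as observed
        total = comb(n + m, n)
        target = abs(u - mu) - 1e-12
        count = 0
        base = n * (n + 1) / 2
        for idx in combinations(range(n + m), n):
            u_perm = sum(idx) + n - base  # ranks are 1-based positions
            if abs(u_perm - mu) >= target:
                count += 1
        return u, count / total
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n + m) * (n + m - 1.0))
    sigma2 = n * m / 12.0 * ((n + m + 1.0) - tie_term)
    if sigma2 <= 0:
        return u, 1.0
    z = (abs(u - mu) - 0.5) / sqrt(sigma2)
    z = max(z, 0.0)
    return u, min(1.0, 2.0 * _norm_sf(z))


# ---------------------------------------------------------------------------
# 2x2 categorical tests
# ---------------------------------------------------------------------------

def _hypergeom_pmf(k: int, n_pop: int, k_pop: int, n_draw: int) -> float:
    return comb(k_pop, k) * comb(n_pop - k_pop, n_draw - k) / comb(n_pop, n_draw)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> float:
    """Two-sided Fisher exact p for a 2x2 table of non-negative counts.

    Sums the hypergeometric probabilities of every table (with the observed
    margins) no more probable than the observed one.  A zero margin makes
    the table degenerate; p = 1 is returned with a warning.
    """
    t = np.asarray(table, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("fisher_exact_2x2 needs a non-negative 2x2 table")
    a, b = int(t[0, 0]), int(t[0, 1])
    c, d = int(t[1, 0]), int(t[1, 1])
    n_pop = a + b + c + d
    row1, col1 = a + b, a + c
    if 0 in (row1, col1, n_pop - row1, n_pop - col1) or n_pop == 0:
        warnings.warn("degenerate 2x2 table (zero margin); Fisher p = 1")
        return 1.0
    lo, hi = max(0, row1 + col1 - n_pop), min(row1, col1)
    p_obs = _hypergeom_pmf(a, n_pop, col1, row1)
    p = sum(
        pk
        for k in range(lo, hi + 1)
        if (pk := _hypergeom_pmf(k, n_pop, col1, row1)) <= p_obs * (1 + 1e-7)
    )
    return min(1.0, p)


def chi2_test(
    table: Sequence[Sequence[int]], continuity: bool = False
) -> tuple[float, float]:
    """Pearson chi-squared test on a 2x2 table (1 df), optionally with
    the Yates continuity correction.  Returns ``(statistic, p)``."""
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValidationError("chi2_test needs a non-negative 2x2 table")
    row = t.sum(axis=1, keepdims=True)
    col = t.sum(axis=0, keepdims=True)
    n = t.sum()
    if n == 0 or (row == 0).any() or (col == 0).any():
        warnings.warn("degenerate 2x2 table (zero margin); chi2 p = 1")
        return 0.0, 1.0
    expected = row @ col / n
    diff = np.abs(t - expected)
    if continuity:
        diff = np.maximum(diff - 0.5, 0.0)
    stat = float(np.sum(diff**2 / expected))
    return stat, float(sst.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# ROC
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RocResult:
    """ROC summary: AUC (with DeLong 95% CI), the cutoff attaining the
    highest sensitivity + specificity, its operating characteristics, and
    the decision direction ('>=' or '<=' predicts the positive class)."""

    auc: float
    auc_ci: tuple[float, float]
    cutoff: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    direction: str


def _confusion_at(scores, labels, cutoff, direction):
    pred = scores >= cutoff if direction == ">=" else scores <= cutoff
    tp = int(np.sum(pred & (labels == 1)))
    fn = int(np.sum(~pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    tn = int(np.sum(~pred & (labels == 0)))
    return tp, fn, fp, tn


def _delong_ci(scores: np.ndarray, labels: np.ndarray, auc: float) -> tuple[float, float]:
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    n1, n0 = len(pos), len(neg)
    psi = (pos[:, None] > neg[None, :]).astype(float)
    psi += 0.5 * (pos[:, None] == neg[None, :])
    v10 = psi.mean(axis=1)
    v01 = psi.mean(axis=0)
    var = (np.var(v10, ddof=1) / n1 if n1 > 1 else 0.0) + (
        np.var(v01, ddof=1) / n0 if n0 > 1 else 0.0
    )
    half = 1.959963984540054 * sqrt(max(var, 0.0))
    return (max(0.0, auc - half), min(1.0, auc + half))


def roc_analysis(
    scores: Sequence[float],
    labels: Sequence[int],
    direction: str = "auto",
) -> RocResult:
    """Empirical ROC analysis with a Youden-style optimal cutoff.

    The AUC is the trapezoidal area over all empirical thresholds (it
    equals the normalized Mann-Whitney U statistic).  The optimal cutoff
    maximizes sensitivity + specificity over the observed score values;
    ties are broken in favour of higher sensitivity, then the smaller
    threshold.  With ``direction='auto'`` the decision direction is chosen
    so that AUC >= 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if set(np.unique(labels)) - {0, 1}:
        raise ValidationError("labels must be binary 0/1")
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    if n1 == 0 or n0 == 0:
        raise ValidationError("roc_analysis requires both classes present")

    # AUC for the '>=' convention via the rank/U identity (midranks for ties)
    ranks = _midranks(scores)
    u = float(np.sum(ranks[labels == 1]) - n1 * (n1 + 1) / 2)
    auc_ge = u / (n1 * n0)
    if direction == "auto":
        direction = ">=" if auc_ge >= 0.5 else "<="
    elif direction not in (">=", "<="):
        raise ValidationError("direction must be 'auto', '>=' or '<='")
    auc = auc_ge if direction == ">=" else 1.0 - auc_ge

    best = None
    for cut in np.unique(scores):
        tp, fn, fp, tn = _confusion_at(scores, labels, cut, direction)
        se = tp / (tp + fn)
        sp = tn / (tn + fp)
        key = (se + sp, se, -cut)
        if best is None or key > best[0]:
            best = (key, cut, (tp, fn, fp, tn), se, sp)
    _, cutoff, (tp, fn, fp, tn), se, sp = best
    ppv = tp / (tp + fp) if tp + fp else float("nan")
    npv = tn / (tn + fn) if tn + fn else float("nan")
    return RocResult(
        auc, _delong_ci(scores, labels, auc), float(cutoff), se, sp, ppv, npv, direction
    )


# ---------------------------------------------------------------------------
# Univariate logistic regression
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LogisticFit:
    """Maximum-likelihood univariate logistic fit.

    The odds ratio is reported per ``increment`` predictor units
    (``odds_ratio = exp(coefficient * increment)``) with a Wald 95% CI and
    two-sided p-value.  ``separated`` flags (quasi-)complete separation,
    where the MLE diverges and the OR is non-finite.
    """

    coefficient: float
    intercept: float
    se: float
    odds_ratio: float
    or_ci: tuple[float, float]
    p_value: float
    increment: float
    separated: bool = False
    degenerate: bool = False


def logistic_fit_univariate(
    x: Sequence[float],
    labels: Sequence[int],
    increment: float = 1.0,
    max_iter: int = 100,
    tol: float = 1e-10,
) -> LogisticFit:
    """Newton-Raphson ML fit of ``logit P(y=1) = a + b*x``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(labels, dtype=float)
    if not np.isfinite(x).all():
        raise ValidationError("predictor contains non-finite values")
    if set(np.unique(y)) - {0.0, 1.0} or len(np.unique(y)) < 2:
        raise ValidationError("labels must contain both classes, coded 0/1")
    if np.ptp(x) == 0:
        warnings.warn("constant predictor: logistic slope undefined")
        return LogisticFit(
            float("nan"), float("nan"), float("nan"), float("nan"),
            (float("nan"), float("nan")), float("nan"), increment, degenerate=True,
        )
    if min(x[y == 1]) > max(x[y == 0]) or max(x[y == 1]) < min(x[y == 0]):
        warnings.warn("complete separation: odds ratio is non-finite")
        sign = 1.0 if min(x[y == 1]) > max(x[y == 0]) else -1.0
        return LogisticFit(
            sign * float("inf"), float("nan"), float("inf"),
            float("inf") if sign > 0 else 0.0,
            (float("nan"), float("nan")), float("nan"), increment, separated=True,
        )
    # standardize for conditioning; back-transform afterwards
    mu, sd = float(np.mean(x)), float(np.std(x))
    z = (x - mu) / sd
    X = np.column_stack([np.ones_like(z), z])
    beta = np.zeros(2)
    for _ in range(max_iter):
        eta = X @ beta
        p = 1.0 / (1.0 + np.exp(-eta))
        w = p * (1.0 - p)
        grad = X.T @ (y - p)
        hess = (X * w[:, None]).T @ X
        try:
            step = np.linalg.solve(hess, grad)
        except np.linalg.LinAlgError:
            break
        beta += step
        if np.max(np.abs(step)) < tol:
            break
    eta = X @ beta
    p = 1.0 / (1.0 + np.exp(-eta))
    w = p * (1.0 - p)
    cov = np.linalg.inv((X * w[:, None]).T @ X)
    slope = beta[1] / sd
    intercept = beta[0] - beta[1] * mu / sd
    se = sqrt(cov[1, 1]) / sd
    z_stat = slope / se if se > 0 else float("inf")
    p_val = min(1.0, 2.0 * _norm_sf(abs(z_stat)))
    lo = np.exp((slope - 1.959963984540054 * se) * increment)
    hi = np.exp((slope + 1.959963984540054 * se) * increment)
    return LogisticFit(
        slope, intercept, se, float(np.exp(slope * increment)),
        (float(lo), float(hi)), p_val, increment,
    )


# ---------------------------------------------------------------------------
# Kaplan-Meier and log-rank
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class KmCurve:
    """Product-limit survival estimate: distinct event times, numbers at
    risk and events there, stepwise survival, and censoring marks."""

    event_times: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    censor_times: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KmCurve:
    """Kaplan-Meier product-limit estimator for one group.

    ``events`` are 1 for an observed event and 0 for right censoring.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if len(t) == 0:
        raise ValidationError("km_estimate requires a non-empty group")
    if (t < 0).any():
        raise ValidationError("survival times must be >= 0")
    if set(np.unique(e)) - {0, 1}:
        raise ValidationError("event flags must be 0/1")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    uniq = np.unique(t[e == 1])
    at_risk = np.array([np.sum(t >= u) for u in uniq], dtype=int)
    d = np.array([np.sum((t == u) & (e == 1)) for u in uniq], dtype=int)
    surv = np.cumprod(1.0 - d / at_risk) if len(uniq) else np.empty(0)
    return KmCurve(uniq, at_risk, d, surv, np.sort(t[e == 0]))


def logrank(
    times: Sequence[float], events: Sequence[int], groups: Sequence[int]
) -> tuple[float, float]:
    """Two-group log-rank test; returns the 1-df chi-squared statistic and
    its p-value."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    g = np.asarray(groups)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValidationError("logrank expects exactly two groups")
    in1 = g == labels[1]
    obs_minus_exp = 0.0
    var = 0.0
    for u in np.unique(t[e == 1]):
        at_risk = np.sum(t >= u)
        at_risk1 = np.sum((t >= u) & in1)
        d = np.sum((t == u) & (e == 1))
        d1 = np.sum((t == u) & (e == 1) & in1)
        obs_minus_exp += d1 - d * at_risk1 / at_risk
        if at_risk > 1:
            var += (
                d * (at_risk1 / at_risk) * (1 - at_risk1 / at_risk)
                * (at_risk - d) / (at_risk - 1)
            )
    if var <= 0:
        return 0.0, 1.0
    stat = obs_minus_exp**2 / var
    return float(stat), float(sst.chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# Cohort-level convenience analyses
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (step-up FDR)."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        i = n - rank_from_top  # 1-based rank of this p-value
        running = min(running, p[idx] * n / i)
        adj[idx] = running
    return adj


def _predictor_columns(cohort: CohortTable) -> dict[str, tuple[np.ndarray, float, str]]:
    """Predictor name -> (values, OR increment, ROC direction hint)."""
    df = cohort.data
    out: dict[str, tuple[np.ndarray, float, str]] = {}
    for ep in ("baseline", "endwpvi"):
        for lead in cohort.leads:
            out[f"fwa_{lead}_{ep}"] = (df[f"fwa_{lead}_{ep}"].to_numpy(), 0.01, ">=")
        out[f"meanfwa_{ep}"] = (df[f"meanfwa_{ep}"].to_numpy(), 0.01, ">=")
    for lead in cohort.leads:
        base = df[f"fwa_{lead}_baseline"].to_numpy()
        end = df[f"fwa_{lead}_endwpvi"].to_numpy()
        out[f"delta_{lead}_pct"] = (100.0 * (end - base) / base, 1.0, "<=")
    base = df["meanfwa_baseline"].to_numpy()
    end = df["meanfwa_endwpvi"].to_numpy()
    out["delta_meanfwa_pct"] = (100.0 * (end - base) / base, 1.0, "<=")
    return out


def compare_groups(cohort: CohortTable, add_bh: bool = False) -> pd.DataFrame:
    """Group-wise medians/IQR and Mann-Whitney p per fWA feature
    (SUCCESS vs FAILURE)."""
    sub = cohort.subset(["SUCCESS", "FAILURE"])
    succ = sub.data["outcome"] == "SUCCESS"
    rows = []
    for name, (vals, _, _) in _predictor_columns(sub).items():
        xs, ys = vals[succ.to_numpy()], vals[~succ.to_numpy()]
        _, p = mann_whitney(xs, ys)
        q = lambda a: np.percentile(a, [50, 25, 75])
        m_s, lo_s, hi_s = q(xs)
        m_f, lo_f, hi_f = q(ys)
        rows.append({
            "feature": name,
            "success_median": m_s, "success_q1": lo_s, "success_q3": hi_s,
            "failure_median": m_f, "failure_q1": lo_f, "failure_q3": hi_f,
            "p_value": p,
        })
    df = pd.DataFrame(rows)
    if add_bh:
        df["p_bh"] = benjamini_hochberg(df["p_value"].to_numpy())
    return df


def predictor_analysis(cohort: CohortTable) -> pd.DataFrame:
    """Per-predictor logistic odds ratio and ROC performance for SUCCESS.

    Mirrors the usual presentation: OR (95% CI) per increment, p, AUC
    (95% CI, percent), optimal cutoff with its direction, SE/SP/PPV/NPV.
    """
    sub = cohort.subset(["SUCCESS", "FAILURE"])
    y = (sub.data["outcome"] == "SUCCESS").to_numpy().astype(int)
    rows = []
    for name, (vals, increment, _) in _predictor_columns(sub).items():
        fit = logistic_fit_univariate(vals, y, increment=increment)
        roc = roc_analysis(vals, y, direction="auto")
        rows.append({
            "predictor": name,
            "or": fit.odds_ratio, "or_lo": fit.or_ci[0], "or_hi": fit.or_ci[1],
            "or_increment": increment, "p_value": fit.p_value,
            "auc_pct": 100 * roc.auc,
            "auc_lo_pct": 100 * roc.auc_ci[0], "auc_hi_pct": 100 * roc.auc_ci[1],
            "direction": roc.direction, "cutoff": roc.cutoff,
            "se": roc.sensitivity, "sp": roc.specificity,
            "ppv": roc.ppv, "npv": roc.npv,
        })
    return pd.DataFrame(rows)
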