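"""Two-threshold decision rule on meanfWA for predicting ablation outcome.

The rule combines the baseline mean f-wave amplitude with its relative
decrease at the end of pulmonary-vein isolation: a patient is predicted to
maintain long-term sinus rhythm (SUCCESS) when

    baseline meanfWA >= baseline_cutoff  (default 0.044 mV)
      OR decrease in meanfWA <= decrease_cutoff  (default 11 %),

and predicted FAILURE only when both branches fail (low baseline amplitude
AND a strong amplitude fall).  Both comparisons are inclusive, and an
amplitude increase (negative decrease) always predicts SUCCESS.

``fit_rule`` learns the two thresholds with a two-stage procedure: the
baseline cutoff is the ROC-optimal (highest sensitivity + specificity)
threshold of baseline meanfWA, and the decrease cutoff is the ROC-optimal
threshold of the relative decrease among the patients below the baseline
cutoff.  This staged construction is this package's documented
interpretation of a two-split decision tree on these two features.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import CohortTable, ValidationError
from .stats import roc_analysis

logger = logging.getLogger(__name__)

__all__ = ["DecisionRule", "RulePerformance", "classify", "evaluate", "fit_rule"]


@dataclass(frozen=True)
class DecisionRule:
    """Thresholds of the two-step rule.

    ``baseline_cutoff`` in mV, ``decrease_cutoff`` in percent of baseline
    (positive = amplitude fall).  Predict SUCCESS if baseline meanfWA >=
    baseline_cutoff OR decrease <= decrease_cutoff.
    """

    baseline_cutoff: float = 0.044
    decrease_cutoff: float = 11.0

    def __post_init__(self) -> None:
        if self.baseline_cutoff <= 0:
            raise ValidationError("baseline_cutoff must be positive (mV)")
        if not np.isfinite(self.decrease_cutoff):
            raise ValidationError("decrease_cutoff must be finite (%)")


@dataclass(frozen=True)
class RulePerformance:
    """Confusion counts (SUCCESS = positive class) and derived metrics.

    Metrics are fractions in [0, 1]; a metric whose denominator is zero is
    reported as NaN.
    """

    tp: int
    fn: int
    fp: int
    tn: int

    @property
    def n(self) -> int:
        return self.tp + self.fn + self.fp + self.tn

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp) if self.tn + self.fp else float("nan")

    @property
    def ppv(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def npv(self) -> float:
        return self.tn / (self.tn + self.fn) if self.tn + self.fn else float("nan")


def classify(
    rule: DecisionRule, baseline_meanfwa: float, decrease_pct: float
) -> str:
    """Apply the two-step rule to one patient; returns 'SUCCESS' or
    'FAILURE'.  Boundary values satisfy the rule (both comparisons are
    inclusive)."""
    if baseline_meanfwa <= 0:
        raise ValidationError("baseline meanfWA must be positive")
    if (
        baseline_meanfwa >= rule.baseline_cutoff
        or decrease_pct <= rule.decrease_cutoff
    ):
        return "SUCCESS"
    return "FAILURE"


def _rule_features(cohort: CohortTable) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    sub = cohort.subset(["SUCCESS", "FAILURE"])
    df = sub.data
    baseline = df["meanfwa_baseline"].to_numpy(dtype=float)
    end = df["meanfwa_endwpvi"].to_numpy(dtype=float)
    if (baseline <= 0).any():
        raise ValidationError("non-positive baseline meanfWA in cohort")
    decrease = -100.0 * (end - baseline) / baseline
    y = (df["outcome"] == "SUCCESS").to_numpy().astype(int)
    return baseline, decrease, y


def evaluate(
    rule: DecisionRule, cohort: CohortTable, return_predictions: bool = False
):
    """Apply the rule to every SUCCESS/FAILURE patient and tally the
    confusion table (SUCCESS = positive class)."""
    baseline, decrease, y = _rule_features(cohort)
    pred = np.array(
        [classify(rule, b, d) == "SUCCESS" for b, d in zip(baseline, decrease)]
    )
    perf = RulePerformance(
        tp=int(np.sum(pred & (y == 1))),
        fn=int(np.sum(~pred & (y == 1))),
        fp=int(np.sum(pred & (y == 0))),
        tn=int(np.sum(~pred & (y == 0))),
    )
    if perf.tp + perf.fn == 0 or perf.fp + perf.tn == 0:
        warnings.warn("single-class cohort: some metrics are undefined (NaN)")
    logger.info(
        "rule (>=%.3f mV | <=%g%%): SE %.2f SP %.2f PPV %.2f NPV %.2f (n=%d)",
        rule.baseline_cutoff, rule.decrease_cutoff,
        perf.sensitivity, perf.specificity, perf.ppv, perf.npv, perf.n,
    )
    if return_predictions:
        labels = np.where(pred, "SUCCESS", "FAILURE")
        return perf, pd.Series(labels, index=cohort.subset(
            ["SUCCESS", "FAILURE"]).data["patient_id"].to_numpy())
    return perf


def fit_rule(cohort: CohortTable) -> DecisionRule:
    """Learn both thresholds from a cohort by the two-stage ROC procedure.

    Stage 1 picks the baseline meanfWA cutoff maximizing sensitivity +
    specificity for SUCCESS; stage 2 repeats this for the relative
    decrease, restricted to the patients below the stage-1 cutoff (the
    only patients whose prediction the second branch can change).  When a
    stage sees a single class, its cutoff falls back to the marginal ROC
    cutoff over the whole cohort, with a warning.
    """
    baseline, decrease, y = _rule_features(cohort)
    if len(np.unique(y)) < 2:
        raise ValidationError("fit_rule requires both outcome classes")
    stage1 = roc_analysis(baseline, y, direction=">=")
    below = baseline < stage1.cutoff
    if below.any() and len(np.unique(y[below])) == 2:
        stage2 = roc_analysis(decrease[below], y[below], direction="<=")
    else:
        warnings.warn(
            "single outcome class below the baseline cutoff; "
            "falling back to the marginal decrease cutoff"
        )
        stage2 = roc_analysis(decrease, y, direction="<=")
    rule = DecisionRule(float(stage1.cutoff), float(stage2.cutoff))
    perf = evaluate(rule, cohort)
    logger.info(
        "fitted rule: baseline >= %.4f mV or decrease <= %.2f%% "
        "(SE %.2f, SP %.2f)",
        rule.baseline_cutoff, rule.decrease_cutoff,
        perf.sensitivity, perf.specificity,
    )
    return rule
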