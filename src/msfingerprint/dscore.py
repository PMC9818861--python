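"""Calibrated D scores and classification metrics.

The classifier emits a probability p for the positive class. The D score is
a linear transform of its log odds,

    D = ln(p / (1 - p)) * lambda + theta,

with lambda and theta fitted on the calibration set so that the mean score
of class A is exactly +1 and of class B exactly -1:

    lambda = 2 / (mu_A - mu_B),    theta = 1 - lambda * mu_A,

where mu_A, mu_B are the class means of the held-out log odds. The decision
threshold is zero: D > 0 calls class A, D < 0 calls class B, D == 0 is
reported as inconclusive. Because the transform is affine, the scores are
invariant to which class the raw probability was oriented toward.

Classifier performance is summarized by the Matthews correlation
coefficient (MCC) of the 2x2 confusion table, +1 for perfect and -1 for
inverted predictions.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .errors import DegenerateCalibrationError


@dataclass(frozen=True)
class CalibrationParams:
    """Fitted affine log-odds transform and the class means it derives from."""

    lambda_: float
    theta: float
    mu_a: float
    mu_b: float


@dataclass(frozen=True)
class DScoreRecord:
    """One sample's probability, log odds, calibrated score and decision."""

    sample_id: str
    cultivar: str
    run_index: int
    p: float
    log_odds: float
    d: float
    decision: str  # "A", "B" or "inconclusive"
    class_label: str | None = None  # ground truth, when known


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def log_odds(p: float) -> float:
    """ln(p / (1 - p)); defined only strictly inside (0, 1)."""
    if not 0.0 < p < 1.0:
        raise ValueError(f"probability must be in (0, 1), got {p}")
    return math.log(p / (1.0 - p))


def fit_calibration(
    log_odds_a: list[float], log_odds_b: list[float]
) -> CalibrationParams:
    """Fit lambda and theta from the calibration set's held-out log odds.

    The inputs are the log odds of all class-A and class-B calibration
    samples (each predicted once, by the fold that held its cultivar out).
    """
    if not log_odds_a or not log_odds_b:
        raise ValueError("both classes need at least one log-odds value")
    mu_a = sum(log_odds_a) / len(log_odds_a)
    mu_b = sum(log_odds_b) / len(log_odds_b)
    if mu_a == mu_b:
        raise DegenerateCalibrationError(
            "class mean log odds coincide; the linear transform is undefined"
        )
    lambda_ = 2.0 / (mu_a - mu_b)
    theta = 1.0 - lambda_ * mu_a
    return CalibrationParams(lambda_=lambda_, theta=theta, mu_a=mu_a, mu_b=mu_b)


def transform(lo: float, params: CalibrationParams) -> float:
    """Apply the fitted affine transform to a log-odds value."""
    return lo * params.lambda_ + params.theta


def decide(d: float) -> str:
    if d > 0:
        return "A"
    if d < 0:
        return "B"
    return "inconclusive"


def compute_dscore(
    p: float,
    params: CalibrationParams,
    *,
    sample_id: str = "",
    cultivar: str = "",
    run_index: int = 0,
    class_label: str | None = None,
) -> DScoreRecord:
    """Log odds, calibrated D score and zero-threshold decision for one p."""
    lo = log_odds(p)
    d = transform(lo, params)
    return DScoreRecord(
        sample_id=sample_id,
        cultivar=cultivar,
        run_index=run_index,
        p=p,
        log_odds=lo,
        d=d,
        decision=decide(d),
        class_label=class_label,
    )


def confusion_counts(
    truths: list[str], decisions: list[str], positive_class: str = "A"
) -> ConfusionCounts:
    """Tally decided samples against ground truth; 'inconclusive' is skipped."""
    if len(truths) != len(decisions):
        raise ValueError("truths and decisions must be aligned")
    tp = tn = fp = fn = 0
    for truth, pred in zip(truths, decisions):
        if pred == "inconclusive":
            continue
        truth_pos = truth == positive_class
        pred_pos = pred == positive_class
        tp += truth_pos and pred_pos
        tn += (not truth_pos) and (not pred_pos)
        fp += (not truth_pos) and pred_pos
        fn += truth_pos and (not pred_pos)
    return ConfusionCounts(tp=tp, tn=tn, fp=fp, fn=fn)


def mcc(c: ConfusionCounts) -> float:
    """Matthews correlation coefficient of a 2x2 confusion table.

    Returns 0 when any marginal is empty (the standard convention for the
    otherwise undefined 0/0 case).
    """
    if c.total == 0:
        raise ValueError("confusion table is empty")
    denom2 = (
        float(c.tp + c.fp) * float(c.tp + c.fn) * float(c.tn + c.fp) * float(c.tn + c.fn)
    )
    if denom2 == 0.0:
        return 0.0
    return (float(c.tp) * c.tn - float(c.fp) * c.fn) / math.sqrt(denom2)
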