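"""Precision parameters of the D score, in the spirit of ISO 5725-3.

Two class-level standard deviations are reported:

* **classification SD** — the sample SD of all individual D scores within a
  class (replicates included). It describes the spread of the class point
  cloud around its calibrated mean of +1 or -1 and drives the
  misclassification risk under a normal model.
* **intermediate SD** — the replicate-to-replicate variation of the same
  cultivar under intermediate conditions (different runs/days), pooled
  across cultivars: sqrt(mean over cultivars of the per-cultivar sample
  variance). For duplicate runs this reduces to sqrt(mean((d1 - d2)^2 / 2)).

The misclassification risk of a class is the normal tail mass on the wrong
side of the zero decision threshold: Phi((0 - mean)/sd) for a class with a
positive mean, 1 - Phi((0 - mean)/sd) for a negative mean. A class mean of
+1 with SD 0.393 gives Phi(-1/0.393) ~ 0.5%.
"""

from __future__ import annotations

import json
import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .dscore import DScoreRecord

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ClassPrecision:
    class_label: str
    n_cultivars: int
    n_scores: int
    mean_d: float
    classification_sd: float
    cultivar_mean_sd: float  # secondary: SD of the cultivar means
    intermediate_sd: float
    misclassification_risk: float


@dataclass(frozen=True)
class PrecisionReport:
    classes: tuple[ClassPrecision, ...]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([asdict(c) for c in self.classes])

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps([asdict(c) for c in self.classes], indent=2))
        return path


def classification_sd(records: list[DScoreRecord]) -> float:
    """Sample SD of all individual D scores of one class."""
    if len(records) < 2:
        raise ValueError("need at least two D scores")
    return float(np.std([r.d for r in records], ddof=1))


def _by_cultivar(records: list[DScoreRecord]) -> dict[str, list[float]]:
    groups: dict[str, list[float]] = defaultdict(list)
    for r in records:
        groups[r.cultivar].append(r.d)
    return groups


def intermediate_sd(records: list[DScoreRecord]) -> float:
    """Pooled within-cultivar SD across replicate measurements.

    Every cultivar needs at least two replicates; the pooled value is the
    square root of the mean per-cultivar sample variance.
    """
    groups = _by_cultivar(records)
    variances = []
    for cultivar, scores in groups.items():
        if len(scores) < 2:
            raise ValueError(f"cultivar {cultivar!r} has fewer than 2 replicates")
        variances.append(np.var(scores, ddof=1))
    return float(np.sqrt(np.mean(variances)))


def misclassification_risk(mean_d: float, sd: float, threshold: float = 0.0) -> float:
    """Normal-model probability of a score falling on the wrong side of the
    decision threshold for a class centred at ``mean_d``."""
    if sd <= 0:
        raise ValueError("sd must be positive")
    if mean_d == threshold:
        warnings.warn("class mean sits exactly on the threshold; risk is 0.5")
        return 0.5
    z = (threshold - mean_d) / sd
    if mean_d > threshold:
        return float(stats.norm.cdf(z))
    return float(1.0 - stats.norm.cdf(z))


def build_precision_report(records: list[DScoreRecord]) -> PrecisionReport:
    """Per-class means, both SDs and normal-model risks for a calibration run."""
    by_class: dict[str, list[DScoreRecord]] = defaultdict(list)
    for r in records:
        if r.class_label is None:
            raise ValueError(f"record {r.sample_id!r} lacks a ground-truth class label")
        by_class[r.class_label].append(r)
    if len(by_class) < 2:
        raise ValueError("need records of both classes")
    out = []
    for cls in sorted(by_class):
        recs = by_class[cls]
        scores = np.array([r.d for r in recs])
        mean_d = float(scores.mean())
        cls_sd = classification_sd(recs)
        cultivar_means = [np.mean(v) for v in _by_cultivar(recs).values()]
        skew, kurt = stats.skew(scores), stats.kurtosis(scores)
        logger.info(
            "class %s: n=%d skew=%.2f excess-kurtosis=%.2f (normality diagnostic)",
            cls, scores.size, skew, kurt,
        )
        out.append(
            ClassPrecision(
                class_label=cls,
                n_cultivars=len(cultivar_means),
                n_scores=scores.size,
                mean_d=mean_d,
                classification_sd=cls_sd,
                cultivar_mean_sd=float(np.std(cultivar_means, ddof=1)),
                intermediate_sd=intermediate_sd(recs),
                misclassification_risk=misclassification_risk(mean_d, cls_sd),
            )
        )
    return PrecisionReport(classes=tuple(out))
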