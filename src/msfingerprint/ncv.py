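"""Nested cross-validation over cultivars.

The calibration design measures each cultivar in replicate; both replicates
of a cultivar always travel together, so a fold holds out one cultivar per
class and trains on all spectra of the remaining cultivars. With 11
cultivars per class and duplicate runs this yields 11 folds, each training
on 40 spectra and testing on 4, and every cultivar is tested exactly once —
the held-out probabilities of the whole calibration set are what the score
calibration is fitted on.

External (unseen) samples are scored by every fold model; the per-model
probabilities are converted to log odds and averaged. The calibrated D score
is linear in log odds, so averaging on the log-odds scale and averaging
per-model D scores are the same operation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np

from . import cnn as _cnn
from .cnn import CnnConfig, TrainedModel
from .dscore import log_odds
from .errors import ShapeMismatchError
from .matrixify import SpectralMatrix
from .simulate import SampleMeta

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FoldSpec:
    """One fold: the held-out cultivar of each class plus the id partition."""

    fold_index: int  # 1-based
    held_out_cultivar_a: str
    held_out_cultivar_b: str
    train_sample_ids: tuple[str, ...]
    test_sample_ids: tuple[str, ...]


@dataclass
class NcvResult:
    """Fold models plus the held-out probability of every calibration sample."""

    folds: list[FoldSpec]
    models: list[TrainedModel]
    held_out_probability: dict[str, float]  # sample_id -> p, predicted once each


def build_folds(
    metas: list[SampleMeta], rng: np.random.Generator | None = None
) -> list[FoldSpec]:
    """Pair cultivars across classes by rank and emit one fold per pair.

    Cultivars are sorted lexicographically within each class and paired by
    rank, which makes the fold order reproducible; pass ``rng`` to use a
    seeded random pairing instead (a robustness-check mode — fold contents
    are the same partition either way, only the pairing changes).
    """
    classes = sorted({m.class_label for m in metas})
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {classes}")
    cls_a, cls_b = classes
    by_class: dict[str, list[str]] = {}
    for cls in classes:
        cultivars = sorted({m.cultivar for m in metas if m.class_label == cls})
        if len(cultivars) < 2:
            raise ValueError(
                f"class {cls!r} has {len(cultivars)} cultivar(s); need >= 2 to hold one out"
            )
        by_class[cls] = cultivars
    if rng is not None:
        for cls in classes:
            by_class[cls] = list(rng.permutation(by_class[cls]))
    n_folds = min(len(by_class[cls_a]), len(by_class[cls_b]))
    folds = []
    for i in range(n_folds):
        held = {by_class[cls_a][i], by_class[cls_b][i]}
        train_ids = tuple(m.sample_id for m in metas if m.cultivar not in held)
        test_ids = tuple(m.sample_id for m in metas if m.cultivar in held)
        folds.append(
            FoldSpec(
                fold_index=i + 1,
                held_out_cultivar_a=by_class[cls_a][i],
                held_out_cultivar_b=by_class[cls_b][i],
                train_sample_ids=train_ids,
                test_sample_ids=test_ids,
            )
        )
    return folds


def run_internal_validation(
    folds: list[FoldSpec],
    matrices: dict[str, SpectralMatrix],
    metas: list[SampleMeta],
    cnn_config: CnnConfig,
) -> NcvResult:
    """Train one model per fold and predict its held-out spectra.

    Per-fold models are independent, each seeded ``base seed + fold index``
    so the whole run is reproducible but folds are not initialization clones.
    """
    meta_by_id = {m.sample_id: m for m in metas}
    for fold in folds:
        for sid in fold.train_sample_ids + fold.test_sample_ids:
            if sid not in matrices:
                raise KeyError(f"no spectral matrix for sample {sid!r}")
    first = matrices[folds[0].train_sample_ids[0]]
    input_shape = first.shape

    models: list[TrainedModel] = []
    held_out: dict[str, float] = {}
    for fold in folds:
        fold_cfg = replace(cnn_config, seed=cnn_config.seed + fold.fold_index)
        model = _cnn.build_model(fold_cfg, input_shape)
        model.fold_index = fold.fold_index
        train_mats = [matrices[sid] for sid in fold.train_sample_ids]
        train_labels = [meta_by_id[sid].class_label for sid in fold.train_sample_ids]
        model = _cnn.train(model, train_mats, train_labels)

        test_mats = [matrices[sid] for sid in fold.test_sample_ids]
        probs = _cnn.predict_probabilities(model, test_mats)
        tp = tn = fp = fn = 0
        for sid, p in zip(fold.test_sample_ids, probs):
            held_out[sid] = float(p)
            truth_pos = meta_by_id[sid].class_label == cnn_config.positive_class
            pred_pos = p > 0.5
            tp += truth_pos and pred_pos
            tn += (not truth_pos) and (not pred_pos)
            fp += (not truth_pos) and pred_pos
            fn += truth_pos and (not pred_pos)
        logger.info(
            "fold %d (%s/%s): %d epochs, test TP=%d TN=%d FP=%d FN=%d",
            fold.fold_index,
            fold.held_out_cultivar_a,
            fold.held_out_cultivar_b,
            len(model.loss_trace),
            tp, tn, fp, fn,
        )
        models.append(model)
    return NcvResult(folds=folds, models=models, held_out_probability=held_out)


def predict_external(
    ncv_result: NcvResult, matrix: SpectralMatrix
) -> tuple[list[float], float]:
    """Score an unseen sample with every fold model.

    Returns the per-model probabilities and the average of their log odds
    (the scale on which the calibrated D score is linear).
    """
    if not ncv_result.models:
        raise ValueError("NCV result contains no models")
    for model in ncv_result.models:
        if matrix.shape != model.input_shape:
            raise ShapeMismatchError(
                f"matrix shape {matrix.shape} does not match model input {model.input_shape}"
            )
    probs = [float(_cnn.predict_probability(m, matrix)) for m in ncv_result.models]
    avg_log_odds = float(np.mean([log_odds(p) for p in probs]))
    return probs, avg_log_odds
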