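"""Youden plots, summary tables and the end-to-end pipeline.

A Youden plot scatters each cultivar's replicate-1 D score against its
replicate-2 D score. With a zero decision threshold the plane reads
directly: quadrant I (both positive) is a concordant class-A call, quadrant
III a concordant class-B call, quadrants II/IV are discordant replicates.
Distance from the diagonal separates within-run from between-run variation.

:func:`run_pipeline` chains every stage — synthesis (or reading mzXML),
integer-mass aggregation, z-normalization, fold construction, per-fold CNN
training, score calibration, D scores, precision parameters and plots —
from one YAML/dict config and writes a report bundle.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, asdict
from pathlib import Path

import matplotlib
import numpy as np
import pandas as pd
import yaml

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from . import dscore as _dscore
from .cnn import CnnConfig
from .errors import MsFingerprintError
from .matrixify import MatrixConfig, aggregate_to_integer_mass, znormalize_scans
from .ncv import build_folds, run_internal_validation
from .precision import build_precision_report
from .simulate import SampleMeta, SimConfig, read_manifest, simulate_dataset
from .io_mzxml import read_ms1_run

logger = logging.getLogger(__name__)

_STYLE = {
    "A": {"marker": "s", "color": "#e08214", "label": "class A"},
    "B": {"marker": "o", "color": "#8c510a", "label": "class B"},
}


@dataclass(frozen=True)
class YoudenPoint:
    cultivar: str
    d_run1: float
    d_run2: float
    class_label: str | None
    quadrant: str  # I, II, III, IV or axis


def _quadrant(d1: float, d2: float) -> str:
    if d1 == 0 or d2 == 0:
        return "axis"
    if d1 > 0 and d2 > 0:
        return "I"
    if d1 < 0 and d2 < 0:
        return "III"
    return "II" if d1 < 0 else "IV"


def make_youden_points(records: list[_dscore.DScoreRecord]) -> list[YoudenPoint]:
    """One point per cultivar from its two replicate D scores (run order fixed
    by ``run_index``). Raises if any cultivar does not have exactly 2 records."""
    groups: dict[str, list[_dscore.DScoreRecord]] = {}
    for r in records:
        groups.setdefault(r.cultivar, []).append(r)
    points = []
    for cultivar in sorted(groups):
        recs = sorted(groups[cultivar], key=lambda r: r.run_index)
        if len(recs) != 2:
            raise ValueError(
                f"cultivar {cultivar!r} has {len(recs)} replicate(s); a Youden plot needs exactly 2"
            )
        points.append(
            YoudenPoint(
                cultivar=cultivar,
                d_run1=recs[0].d,
                d_run2=recs[1].d,
                class_label=recs[0].class_label,
                quadrant=_quadrant(recs[0].d, recs[1].d),
            )
        )
    return points


def render_youden_plot(
    points: list[YoudenPoint],
    out_path: str | Path,
    zoom: tuple[float, float, float, float] | None = None,
) -> Path:
    """Scatter the replicate D scores with zero-threshold lines.

    ``zoom`` = (xmin, xmax, ymin, ymax) adds a magnified inset of that
    region. Output format follows the file extension (SVG or PNG); SVG
    output is byte-stable for fixed input.
    """
    if not points:
        raise ValueError("no points to plot")
    plt.rcParams["svg.hashsalt"] = "msfingerprint"
    fig, ax = plt.subplots(figsize=(6, 6))
    _scatter(ax, points)
    ax.axhline(0.0, color="0.4", lw=0.8, ls="--")
    ax.axvline(0.0, color="0.4", lw=0.8, ls="--")
    ax.set_xlabel("D score run 1")
    ax.set_ylabel("D score run 2")
    ax.legend(loc="upper left", frameon=False)
    ax.set_aspect("equal", adjustable="datalim")
    if zoom is not None:
        inset = ax.inset_axes([0.58, 0.08, 0.38, 0.38])
        _scatter(inset, points)
        inset.set_xlim(zoom[0], zoom[1])
        inset.set_ylim(zoom[2], zoom[3])
        inset.tick_params(labelsize=7)
        ax.indicate_inset_zoom(inset, edgecolor="0.5")
    out_path = Path(out_path)
    fig.savefig(out_path, metadata={"Date": None} if out_path.suffix == ".svg" else None)
    plt.close(fig)
    return out_path


def _scatter(ax, points: list[YoudenPoint]) -> None:
    seen = set()
    for p in points:
        style = _STYLE.get(p.class_label or "", {"marker": "^", "color": "0.3", "label": "unknown"})
        label = style["label"] if p.class_label not in seen else None
        seen.add(p.class_label)
        ax.scatter(p.d_run1, p.d_run2, marker=style["marker"],
                   facecolors="none", edgecolors=style["color"], label=label)


def render_matrix_heatmap(
    values: np.ndarray, out_path: str | Path, gamma: float = 0.3
) -> Path:
    """Power-law-normalized heatmap of a raw spectral matrix (visual QC)."""
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.imshow(
        np.asarray(values) ** gamma if np.all(values >= 0) else values,
        aspect="auto", origin="lower", cmap="viridis", interpolation="nearest",
    )
    ax.set_xlabel("integer m/z bin")
    ax.set_ylabel("scan")
    out_path = Path(out_path)
    fig.savefig(out_path)
    plt.close(fig)
    return out_path


# ---------------------------------------------------------------------------
# end-to-end pipeline


def _load_config(config: str | Path | dict) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run_pipeline(config: str | Path | dict, out_dir: str | Path | None = None) -> dict:
    """Execute the full dry-lab chain and return a machine-readable summary.

    The config is a dict or YAML file with blocks ``simulate`` (generator
    parameters) *or* ``inputs`` (``manifest`` + ``data_dir`` of mzXML files),
    plus optional ``matrix``, ``cnn`` and ``report`` blocks. When ``out_dir``
    is given (or set in the config) the bundle — held-out probabilities,
    calibration parameters, D-score table, precision report, Youden plot and
    ``summary.json`` — is written there.
    """
    t_start = time.time()
    cfg = _load_config(config)
    out_dir = Path(out_dir or cfg.get("output_dir")) if (out_dir or cfg.get("output_dir")) else None

    # --- inputs -----------------------------------------------------------
    if "simulate" in cfg:
        sim_cfg = SimConfig(**cfg["simulate"])
        runs, metas = simulate_dataset(sim_cfg)
        default_scans = sim_cfg.n_scans
    elif "inputs" in cfg:
        manifest = Path(cfg["inputs"]["manifest"])
        data_dir = Path(cfg["inputs"].get("data_dir", manifest.parent))
        metas = read_manifest(manifest)
        _validate_metas(metas)
        runs = [
            read_ms1_run(data_dir / f"{m.sample_id}.mzXML", m.sample_id, m.run_index)
            for m in metas
        ]
        default_scans = max(r.n_scans for r in runs)
    else:
        raise MsFingerprintError("config needs a 'simulate' or 'inputs' block")
    _validate_metas(metas)

    matrix_cfg = MatrixConfig(**{"n_scans": default_scans, **cfg.get("matrix", {})})
    cnn_cfg = CnnConfig(**_tupled(cfg.get("cnn", {})))

    # --- prepare ----------------------------------------------------------
    matrices = {}
    for run in runs:
        raw = aggregate_to_integer_mass(run, matrix_cfg)
        matrices[run.sample_id] = znormalize_scans(raw)
    logger.info("prepared %d matrices of shape %s", len(matrices), matrix_cfg.n_scans)

    # --- NCV + calibration ------------------------------------------------
    folds = build_folds(metas)
    ncv_result = run_internal_validation(folds, matrices, metas, cnn_cfg)

    meta_by_id = {m.sample_id: m for m in metas}
    classes = sorted({m.class_label for m in metas})
    lo = {sid: _dscore.log_odds(p) for sid, p in ncv_result.held_out_probability.items()}
    lo_a = [lo[sid] for sid in lo if meta_by_id[sid].class_label == classes[0]]
    lo_b = [lo[sid] for sid in lo if meta_by_id[sid].class_label == classes[1]]
    params = _dscore.fit_calibration(lo_a, lo_b)

    records = [
        _dscore.compute_dscore(
            ncv_result.held_out_probability[m.sample_id],
            params,
            sample_id=m.sample_id,
            cultivar=m.cultivar,
            run_index=m.run_index,
            class_label=m.class_label,
        )
        for m in metas
    ]
    # decisions are on the calibrated scale where classes[0] is positive
    counts = _dscore.confusion_counts(
        [r.class_label for r in records],
        [{"A": classes[0], "B": classes[1]}.get(r.decision, r.decision) for r in records],
        positive_class=classes[0],
    )
    mcc_value = _dscore.mcc(counts)
    precision_report = build_precision_report(records)
    points = make_youden_points(records)

    summary = {
        "n_calibration_records": len(records),
        "n_folds": len(folds),
        "classes": classes,
        "lambda": params.lambda_,
        "theta": params.theta,
        "mu_a": params.mu_a,
        "mu_b": params.mu_b,
        "confusion": asdict(counts),
        "mcc": mcc_value,
        "precision": [asdict(c) for c in precision_report.classes],
        "runtime_s": round(time.time() - t_start, 2),
    }

    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            [
                {"sample_id": m.sample_id, "cultivar": m.cultivar,
                 "class_label": m.class_label, "run_index": m.run_index,
                 "p": ncv_result.held_out_probability[m.sample_id]}
                for m in metas
            ]
        ).to_csv(out_dir / "heldout_probabilities.csv", index=False)
        (out_dir / "calibration.json").write_text(json.dumps(asdict(params), indent=2))
        pd.DataFrame([asdict(r) for r in records]).to_csv(out_dir / "dscores.csv", index=False)
        precision_report.to_frame().to_csv(out_dir / "precision.csv", index=False)
        precision_report.to_json(out_dir / "precision.json")
        render_youden_plot(points, out_dir / "youden.svg",
                           zoom=tuple(cfg.get("report", {}).get("zoom", ())) or None)
        (out_dir / "summary.json").write_text(json.dumps(summary, indent=2))
        logger.info("report bundle written to %s", out_dir)
    return summary


def _validate_metas(metas: list[SampleMeta]) -> None:
    missing = [m.sample_id for m in metas if not m.class_label or str(m.class_label) == "nan"]
    if missing:
        raise MsFingerprintError(f"samples without class label: {missing[:5]}")
    seen = set()
    for m in metas:
        key = (m.cultivar, m.run_index)
        if key in seen:
            raise MsFingerprintError(f"duplicate (cultivar, run_index): {key}")
        seen.add(key)


def _tupled(cnn_block: dict) -> dict:
    out = dict(cnn_block)
    for key in ("filters_per_layer", "kernel_size", "pool_size"):
        if key in out:
            out[key] = tuple(out[key])
    return out
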