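"""Synthetic two-class LC-HRMS fingerprint datasets.

The generator emulates the hierarchical structure a cultivar-authentication
study produces: two classes (A and B, e.g. spelt and wheat), a set of named
cultivars per class, and duplicate measurement runs per cultivar. Each
dataset draws a common set of chromatographic peaks — shared peptide-like
features present in both classes plus class-specific marker peaks that are
intensified by a factor ``1 + class_effect`` in their own class. Variation
enters at three levels, mirroring the study design:

* cultivar level — per-cultivar, per-peak log-normal intensity multipliers;
* run level — per-run, per-peak log-normal multipliers plus a whole-scan
  retention-time shift shared by all peaks of the run (replicates are
  measured on different days, so the chromatography drifts);
* scan level — small m/z scatter per centroid (< 0.2 Da, absorbed by
  integer-mass aggregation) and additive intensity noise truncated at zero.

Peaks are Gaussian in the retention-time (scan) dimension and a single
centroid per scan in m/z.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .io_mzxml import CentroidScan, RawRun, write_mzxml


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic dataset generator.

    Defaults reproduce the calibration-set design this package targets:
    2 classes x 11 cultivars x duplicate runs = 44 spectra, m/z 400-1200,
    a strong class signature (markers tripled in their own class) and
    cultivar variation well above run-to-run variation.
    """

    n_cultivars_per_class: int = 11
    n_replicates: int = 2
    n_scans: int = 200
    mz_min: int = 400
    mz_max: int = 1200
    n_shared_peaks: int = 60
    n_marker_peaks: int = 10
    class_effect: float = 2.0
    cultivar_sd: float = 0.2
    run_sd: float = 0.05
    rt_jitter_sd: float = 1.0
    baseline_noise: float = 2.0
    chrom_width: float = 3.0  # SD of the Gaussian elution profile, in scans
    mz_scatter: float = 0.05  # per-scan centroid m/z scatter (Da)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_cultivars_per_class < 1 or self.n_replicates < 1 or self.n_scans < 1:
            raise ValueError("counts must be >= 1")
        if self.n_shared_peaks < 1:
            raise ValueError("need at least one shared peak")
        if self.n_marker_peaks < 0:
            raise ValueError("n_marker_peaks must be >= 0")
        if self.class_effect < 0:
            raise ValueError("class_effect must be >= 0")
        for name in ("cultivar_sd", "run_sd", "rt_jitter_sd", "baseline_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be < mz_max")


@dataclass(frozen=True)
class SampleMeta:
    """Identity of one measured run: which cultivar, class and replicate."""

    sample_id: str
    cultivar: str
    class_label: str
    run_index: int


CLASSES = ("A", "B")


def _draw_peaks(rng: np.random.Generator, n: int, config: SimConfig) -> dict:
    margin_rt = 4.0 * config.chrom_width + 4.0 * config.rt_jitter_sd + 1.0
    lo = min(margin_rt, config.n_scans / 2.0 - 0.5)
    return {
        "mz": rng.uniform(config.mz_min + 1.0, config.mz_max - 1.0, size=n),
        "rt": rng.uniform(lo, config.n_scans - lo, size=n),
        "amplitude": 10.0 ** rng.uniform(2.0, 3.0, size=n),
    }


def simulate_dataset(config: SimConfig) -> tuple[list[RawRun], list[SampleMeta]]:
    """Generate all runs of a two-class calibration design.

    Fully reproducible from ``config.seed``: peak locations are drawn once
    per dataset, cultivar multipliers once per cultivar, run noise and the
    retention-time shift once per replicate run.

    Returns ``n_classes * n_cultivars_per_class * n_replicates`` runs plus
    aligned metadata.
    """
    rng = np.random.default_rng(config.seed)

    shared = _draw_peaks(rng, config.n_shared_peaks, config)
    markers = {c: _draw_peaks(rng, config.n_marker_peaks, config) for c in CLASSES}

    # one flat peak table: m/z, Rt center, base amplitude, owning class ('' = shared)
    peak_mz = np.concatenate([shared["mz"]] + [markers[c]["mz"] for c in CLASSES])
    peak_rt = np.concatenate([shared["rt"]] + [markers[c]["rt"] for c in CLASSES])
    peak_amp = np.concatenate([shared["amplitude"]] + [markers[c]["amplitude"] for c in CLASSES])
    peak_owner = np.concatenate(
        [np.repeat("", config.n_shared_peaks)]
        + [np.repeat(c, config.n_marker_peaks) for c in CLASSES]
    )
    n_peaks = peak_mz.size

    runs: list[RawRun] = []
    metas: list[SampleMeta] = []
    half_window = int(np.ceil(4.0 * config.chrom_width))

    for class_label in CLASSES:
        for ci in range(config.n_cultivars_per_class):
            cultivar = f"{class_label}{ci + 1:02d}"
            cult_mult = np.exp(rng.normal(0.0, config.cultivar_sd, size=n_peaks))
            class_mult = np.where(
                peak_owner == class_label, 1.0 + config.class_effect, 1.0
            )
            for run_index in range(1, config.n_replicates + 1):
                run_mult = np.exp(rng.normal(0.0, config.run_sd, size=n_peaks))
                rt_shift = int(np.rint(rng.normal(0.0, config.rt_jitter_sd)))
                amp = peak_amp * class_mult * cult_mult * run_mult
                centers = peak_rt + rt_shift

                per_scan_mz: list[list[float]] = [[] for _ in range(config.n_scans)]
                per_scan_int: list[list[float]] = [[] for _ in range(config.n_scans)]
                for k in range(n_peaks):
                    c = centers[k]
                    s0 = max(0, int(np.floor(c)) - half_window)
                    s1 = min(config.n_scans - 1, int(np.ceil(c)) + half_window)
                    if s1 < s0:
                        continue
                    scans_k = np.arange(s0, s1 + 1)
                    profile = amp[k] * np.exp(
                        -0.5 * ((scans_k - c) / config.chrom_width) ** 2
                    )
                    scatter = rng.normal(0.0, config.mz_scatter, size=scans_k.size)
                    noise = rng.normal(0.0, config.baseline_noise, size=scans_k.size)
                    inten = np.maximum(profile + noise, 0.0)
                    for s, m, v in zip(scans_k, peak_mz[k] + scatter, inten):
                        if v > 0:
                            per_scan_mz[s].append(m)
                            per_scan_int[s].append(v)

                sample_id = f"{cultivar}_r{run_index}"
                scans = []
                for s in range(config.n_scans):
                    mz = np.asarray(per_scan_mz[s])
                    inten = np.asarray(per_scan_int[s])
                    if mz.size:
                        order = np.argsort(mz, kind="stable")
                        mz, inten = mz[order], inten[order]
                        uniq, inverse = np.unique(mz, return_inverse=True)
                        if uniq.size < mz.size:
                            summed = np.zeros(uniq.size)
                            np.add.at(summed, inverse, inten)
                            mz, inten = uniq, summed
                    scans.append(
                        CentroidScan(
                            scan_index=s,
                            retention_time=float(s),
                            ms_level=1,
                            mz=mz,
                            intensity=inten,
                        )
                    )
                runs.append(RawRun(sample_id=sample_id, run_index=run_index, scans=scans))
                metas.append(
                    SampleMeta(
                        sample_id=sample_id,
                        cultivar=cultivar,
                        class_label=class_label,
                        run_index=run_index,
                    )
                )
    return runs, metas


def emit_dataset(
    runs: list[RawRun], metas: list[SampleMeta], out_dir: str | Path
) -> Path:
    """Write one mzXML per run plus a CSV manifest; returns the manifest path."""
    if len(runs) != len(metas):
        raise ValueError("runs and metas must be aligned")
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for run, meta in zip(runs, metas):
        if run.sample_id != meta.sample_id:
            raise ValueError(f"run/meta mismatch: {run.sample_id} vs {meta.sample_id}")
        path = out_dir / f"{meta.sample_id}.mzXML"
        write_mzxml(run, path)
        rows.append(
            {
                "sample_id": meta.sample_id,
                "cultivar": meta.cultivar,
                "class_label": meta.class_label,
                "run_index": meta.run_index,
                "path": path.name,
            }
        )
    manifest = out_dir / "manifest.csv"
    pd.DataFrame(rows).to_csv(manifest, index=False)
    return manifest


def read_manifest(path: str | Path) -> list[SampleMeta]:
    """Load sample metadata back from a manifest written by :func:`emit_dataset`."""
    df = pd.read_csv(path, dtype={"sample_id": str, "cultivar": str, "class_label": str})
    return [
        SampleMeta(
            sample_id=r.sample_id,
            cultivar=r.cultivar,
            class_label=r.class_label,
            run_index=int(r.run_index),
        )
        for r in df.itertuples()
    ]
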