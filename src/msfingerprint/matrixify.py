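"""Integer-mass spectral matrices.

A run of centroided MS1 scans becomes a fixed-size 2-D "image": rows are
scans (retention time), columns are 1-Da m/z bins. The matrix is what the
convolutional classifier consumes, after each scan (row) has been
z-normalized. No peak alignment, baseline correction or feature selection is
applied — the whole fingerprint enters the model as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .errors import ContractError, EmptyRunError, ShapeMismatchError
from .io_mzxml import RawRun


@dataclass(frozen=True)
class MatrixConfig:
    """Geometry of the spectral matrix.

    ``mz_min``/``mz_max`` are inclusive integer-Da bounds, so the number of
    columns is ``mz_max - mz_min + 1`` (400–1200 Da gives 801 bins). Runs
    longer than ``n_scans`` are truncated at the end; shorter runs are padded
    with zero rows.
    """

    mz_min: int = 400
    mz_max: int = 1200
    n_scans: int = 1375

    def __post_init__(self) -> None:
        if self.mz_min >= self.mz_max:
            raise ValueError("mz_min must be < mz_max")
        if self.n_scans < 1:
            raise ValueError("n_scans must be >= 1")

    @property
    def n_bins(self) -> int:
        return self.mz_max - self.mz_min + 1


@dataclass
class SpectralMatrix:
    """2-D intensity grid of shape (n_scans, n_bins) for one sample run."""

    sample_id: str
    run_index: int
    values: np.ndarray
    mz_min: int
    mz_max: int
    normalized: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (scans x bins)")
        if self.values.shape[1] != self.mz_max - self.mz_min + 1:
            raise ValueError("column count must equal mz_max - mz_min + 1")

    @property
    def n_scans(self) -> int:
        return self.values.shape[0]

    @property
    def n_bins(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """Round to nearest integer, halves away from zero (m/z is positive here)."""
    return np.where(x >= 0, np.floor(x + 0.5), np.ceil(x - 0.5))


def aggregate_to_integer_mass(run: RawRun, config: MatrixConfig) -> SpectralMatrix:
    """Sum centroid intensities into integer-Da bins, one row per scan.

    A peak lands in the bin its m/z rounds to (nearest integer, half away
    from zero); peaks rounding outside ``[mz_min, mz_max]`` are dropped.
    """
    if run.n_scans == 0:
        raise EmptyRunError(f"run {run.sample_id!r} has no scans")
    values = np.zeros((config.n_scans, config.n_bins), dtype=np.float64)
    for row, scan in enumerate(run.scans[: config.n_scans]):
        if scan.n_peaks == 0:
            continue
        bins = _round_half_away(scan.mz).astype(np.int64) - config.mz_min
        keep = (bins >= 0) & (bins < config.n_bins)
        np.add.at(values[row], bins[keep], scan.intensity[keep])
    return SpectralMatrix(
        sample_id=run.sample_id,
        run_index=run.run_index,
        values=values,
        mz_min=config.mz_min,
        mz_max=config.mz_max,
        normalized=False,
    )


def znormalize_scans(matrix: SpectralMatrix) -> SpectralMatrix:
    """Standardize each scan (row) to mean 0 and population SD 1.

    Constant rows — including the zero rows used to pad short runs — have no
    scale and are mapped to all-zero rows. Raises :class:`ContractError` on
    an already-normalized matrix: the transform is defined on intensities.
    """
    if matrix.normalized:
        raise ContractError("matrix is already z-normalized")
    v = matrix.values
    mean = v.mean(axis=1, keepdims=True)
    sd = v.std(axis=1, keepdims=True)  # population SD
    out = np.where(sd > 0, (v - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return replace(matrix, values=out, normalized=True)


def make_artificial_mix(
    major: SpectralMatrix, minor: SpectralMatrix, w_major: float
) -> SpectralMatrix:
    """Weighted elementwise sum of two raw matrices (in-silico blend).

    ``w_major`` of the major component plus ``1 - w_major`` of the minor —
    e.g. 0.9 emulates a 90/10 blend. Defined on raw aggregated intensities
    only; normalize after mixing.
    """
    if not 0.0 <= w_major <= 1.0:
        raise ValueError("w_major must be in [0, 1]")
    if major.normalized or minor.normalized:
        raise ContractError("mixing is defined on raw intensities, not normalized matrices")
    if major.shape != minor.shape or (major.mz_min, major.mz_max) != (minor.mz_min, minor.mz_max):
        raise ShapeMismatchError("matrices must share shape and m/z bounds")
    values = w_major * major.values + (1.0 - w_major) * minor.values
    sample_id = f"mix[{w_major:g}*{major.sample_id}+{1.0 - w_major:g}*{minor.sample_id}]"
    return SpectralMatrix(
        sample_id=sample_id,
        run_index=major.run_index,
        values=values,
        mz_min=major.mz_min,
        mz_max=major.mz_max,
        normalized=False,
    )


# ---------------------------------------------------------------------------
# persistence

def _key(m: SpectralMatrix) -> str:
    return f"{m.sample_id}__run{m.run_index}"


def save_matrices(matrices: list[SpectralMatrix], path: str | Path) -> Path:
    """Persist matrices to an HDF5 container, one dataset per sample run."""
    path = Path(path)
    with h5py.File(path, "w") as fh:
        for m in matrices:
            ds = fh.create_dataset(_key(m), data=m.values.astype(np.float32))
            ds.attrs["sample_id"] = m.sample_id
            ds.attrs["run_index"] = m.run_index
            ds.attrs["mz_min"] = m.mz_min
            ds.attrs["mz_max"] = m.mz_max
            ds.attrs["normalized"] = m.normalized
    return path


def load_matrices(path: str | Path) -> list[SpectralMatrix]:
    with h5py.File(Path(path), "r") as fh:
        out = []
        for key in fh:
            ds = fh[key]
            out.append(
                SpectralMatrix(
                    sample_id=str(ds.attrs["sample_id"]),
                    run_index=int(ds.attrs["run_index"]),
                    values=np.asarray(ds[...], dtype=np.float64),
                    mz_min=int(ds.attrs["mz_min"]),
                    mz_max=int(ds.attrs["mz_max"]),
                    normalized=bool(ds.attrs["normalized"]),
                )
            )
    return out


def qc_sums(matrices: list[SpectralMatrix]) -> pd.DataFrame:
    """Per-sample total, row-sum and column-sum summaries for quick QC export."""
    rows = []
    for m in matrices:
        rows.append(
            {
                "sample_id": m.sample_id,
                "run_index": m.run_index,
                "total": float(m.values.sum()),
                "max_row_sum": float(m.values.sum(axis=1).max()),
                "max_col_sum": float(m.values.sum(axis=0).max()),
                "nonzero_cells": int(np.count_nonzero(m.values)),
            }
        )
    return pd.DataFrame(rows)
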