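import numpy as np
import pytest

from msfingerprint.io_mzxml import CentroidScan, RawRun
from msfingerprint.matrixify import MatrixConfig, SpectralMatrix
from msfingerprint.simulate import SimConfig


@pytest.fixture
def three_scan_run() -> RawRun:
    scans = [
        CentroidScan(0, 0.0, 1, np.array([400.1, 500.2, 500.4]), np.array([10.0, 100.0, 50.0])),
        CentroidScan(1, 1.0, 1, np.array([], dtype=float), np.array([], dtype=float)),
        CentroidScan(2, 2.5, 1, np.array([450.49, 1199.6]), np.array([7.0, 3.0])),
    ]
    return RawRun(sample_id="s1", run_index=1, scans=scans)


@pytest.fixture
def small_matrix_config() -> MatrixConfig:
    return MatrixConfig(mz_min=400, mz_max=500, n_scans=8)


def raw_matrix(values, sample_id="m", run_index=1, mz_min=400) -> SpectralMatrix:
    values = np.asarray(values, dtype=float)
    return SpectralMatrix(
        sample_id=sample_id,
        run_index=run_index,
        values=values,
        mz_min=mz_min,
        mz_max=mz_min + values.shape[1] - 1,
        normalized=False,
    )


@pytest.fixture
def tiny_sim_config() -> SimConfig:
    """Small everything: fast to simulate and train on, still hierarchical."""
    return SimConfig(
        n_cultivars_per_class=3,
        n_scans=64,
        mz_min=400,
        mz_max=500,
        n_shared_peaks=12,
        n_marker_peaks=4,
        seed=11,
    )
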