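import numpy as np
import pytest

from rsfusion import BoldVolume, BrainMask


def make_volume(data, tr=2.0, voxel=(3.0, 3.0, 3.0)) -> BoldVolume:
    return BoldVolume(np.asarray(data, dtype=float), voxel, tr)


def volume_from_series(series, grid=(4, 4, 4), tr=2.0) -> BoldVolume:
    """Broadcast one time series to every voxel of a small grid."""
    series = np.asarray(series, dtype=float)
    data = np.broadcast_to(series, (*grid, series.size)).copy()
    return make_volume(data, tr=tr)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def full_mask_444():
    return BrainMask(np.ones((4, 4, 4), dtype=bool))
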