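import numpy as np
import pytest

from syncflow.types import BoldDataset, FeatureSeries


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_series(values, dt=1.0, t0=0.0, name="s"):
    return FeatureSeries(name=name, t0=t0, dt=dt, values=np.asarray(values, float))


def make_bold(data, tr=3.0, subject_id="sub", mask=None):
    """Wrap an (n_voxels, n_volumes) array in a BoldDataset on a flat grid."""
    data = np.asarray(data, float)
    if mask is None:
        mask = np.ones((data.shape[0], 1, 1), dtype=bool)
    return BoldDataset(subject_id=subject_id, data=data, mask=mask, tr=tr)


@pytest.fixture
def small_noise_bold(rng):
    """Four subjects of independent noise on a 8-voxel grid, 30 volumes."""
    return [
        make_bold(rng.standard_normal((8, 30)), subject_id=f"sub-{i}")
        for i in range(4)
    ]
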