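import numpy as np
import pytest

import boldlag as bl

TR = 2.08
DT_FINE = TR / 32


@pytest.fixture(scope="session")
def single_thread_epoch():
    """Noiseless single-source epoch with a known per-voxel delay field."""
    rng = np.random.default_rng(42)
    n = 12
    delays = rng.uniform(-0.9, 0.9, size=(n, 1))
    src = bl.generate_sources(1, 8192, DT_FINE, alpha=1.0, seed=7)
    plan = bl.LagPlan(
        weights=np.ones((n, 1)), delays=delays, noise_sd=0.0, n_frames=150
    )
    epoch = bl.synthesize_epoch(src, plan, seed=3)
    return epoch, delays[:, 0]


def make_noise_epoch(seed: int, n_voxels: int = 8, n_frames: int = 160,
                     baseline: float = 1000.0) -> bl.TimeSeriesEpoch:
    rng = np.random.default_rng(seed)
    data = baseline + rng.standard_normal((n_voxels, n_frames))
    return bl.TimeSeriesEpoch(data=data, tr=TR)
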