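import numpy as np
import pytest

from pimflux import DetectParams, SimConfig, simulate_timelapse


@pytest.fixture(scope="session")
def small_wt_run():
    """One small wild-type time-lapse shared across read-only tests."""
    cfg = SimConfig(
        image_shape=(256, 256), n_frames=24, frame_interval=10.0,
        n_cells=1, clusters_per_cell_mean=30, min_separation=10,
        clearance_rate=0.15, entry_delay_min=0.0,
        quench_halftime=3.0, egfp_lysosomal_decay_rate=0.5,
        drift_speed=0.0, drift_jitter=0.0, seed=11,
    )
    stack, log = simulate_timelapse(cfg)
    return cfg, stack, log


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def live_params():
    return DetectParams(snr=20.0)
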