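import numpy as np
import pytest

from posturekit.io_formats import RawRecording, RunConfig
from posturekit.synthetic_data import SwaySimConfig, render_devices, simulate_sway


@pytest.fixture
def run_cfg() -> RunConfig:
    return RunConfig()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_corner_recording(values_by_channel, rate=40.0, jitter=None):
    """Small corner-board recording from per-channel values (arrays or scalars)."""
    channels = {c: np.atleast_1d(np.asarray(v, dtype=float))
                for c, v in values_by_channel.items()}
    n = max(v.size for v in channels.values())
    channels = {c: np.full(n, v[0]) if v.size == 1 else v for c, v in channels.items()}
    t = np.arange(n) / rate if jitter is None else jitter
    return RawRecording("corner_board", rate, t, channels)


@pytest.fixture
def noise_free_trial(run_cfg):
    """One noise-free, lag-free synthetic dual-device trial with its truth."""
    sim = SwaySimConfig(seed=7, duration_s=30.0, board_noise_sd_n=0.0,
                        plate_noise_sd_n=0.0, board_ml_noise_sd_n=0.0,
                        jitter_sd_ms=0.0)
    truth = simulate_sway(sim)
    board, plate = render_devices(truth, sim, run_cfg)
    return sim, truth, board, plate
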