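"""Shared fixtures: small deterministic simulation worlds."""

import numpy as np
import pytest

from dopafilm.simcore import (
    ReleaseSchedule,
    SimulationConfig,
    StimTrain,
    generate_dataset,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20260917)


def single_site_config(**overrides) -> SimulationConfig:
    """Small noiseless single-site world used across kinetic tests."""
    defaults = dict(
        grid_shape=(32, 32),
        frame_rate_hz=10.0,
        duration_s=15.0,
        k_uptake_s=25.0,
        sigma_release_um=0.54,
        quantal_cv=0.0,
        shot_noise=False,
        read_noise_sd=0.0,
        seed=0,
    )
    defaults.update(overrides)
    return SimulationConfig(**defaults)


def single_site_movie(cfg: SimulationConfig, event_times, seed=0):
    """One centered site firing single quanta at the given times."""
    px = cfg.pixel_size_um
    x0 = (cfg.grid_shape[1] // 2) * px
    y0 = (cfg.grid_shape[0] // 2) * px
    trains = [
        StimTrain(t, n_pulses=1, pulse_rate_hz=1.0, p_release=1.0) for t in event_times
    ]
    schedule = ReleaseSchedule(sites=[(x0, y0, True)], evoked=trains)
    return generate_dataset(cfg, schedule, seed=seed)


def site_box_trace(movie, x_um, y_um, halfwidth_px=6):
    """Mean raw-F trace in a box around a known site (ground-truth ROI)."""
    px = movie.pixel_size_um
    cx, cy = int(round(x_um / px)), int(round(y_um / px))
    h, w = movie.frames.shape[1:]
    sl = np.s_[
        :, max(0, cy - halfwidth_px) : min(h, cy + halfwidth_px + 1),
        max(0, cx - halfwidth_px) : min(w, cx + halfwidth_px + 1),
    ]
    return movie.frames[sl].mean(axis=(1, 2))
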