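"""Raw movie -> F0 and dFF via blur + leaky cumulative minimum + smoothing.

The per-pixel baseline F0 is built in three steps: a light spatial blur of
the raw movie, a leaky cumulative minimum through time (a running minimum
that is allowed to relax upward at a small per-frame rate, so it tracks
slow drift without following transients), and repeated temporal lowpass
filtering clipped to that minimum trace so the final baseline is smooth
while never exceeding the minima. dFF = (F_blurred - F0) / F0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np
from scipy.ndimage import gaussian_filter, gaussian_filter1d

from .errors import ConfigError, DataError
from .simcore import MovieStack

__all__ = [
    "BaselineParams",
    "BaselineResult",
    "gaussian_blur_xy",
    "leaky_cummin",
    "smooth_baseline",
    "compute_dff",
]


@dataclass(frozen=True)
class BaselineParams:
    blur_sigma_px: float = 0.5
    leak_eta: float = 0.01  # upward relaxation per frame, in (0, 1)
    pre_smooth_sigma_frames: float = 3.0  # temporal smoothing before the cummin
    lowpass_sigma_frames: float = 10.0
    n_lowpass_iters: int = 60
    converge_tol: float = 1e-4  # of the stack max
    restore_lambda: float = 0.1  # pull toward the minima; anchors the iteration
    f0_floor: float = 1.0  # counts; guards division on dark pixels

    def __post_init__(self):
        if self.blur_sigma_px < 0:
            raise ConfigError("blur_sigma_px must be >= 0")
        if not (0.0 < self.leak_eta < 1.0):
            raise ConfigError("leak_eta must be in (0, 1)")
        if self.lowpass_sigma_frames <= 0 or self.pre_smooth_sigma_frames < 0:
            raise ConfigError("temporal smoothing sigmas must be positive")
        if self.n_lowpass_iters < 1:
            raise ConfigError("n_lowpass_iters must be >= 1")
        if self.restore_lambda <= 0:
            raise ConfigError("restore_lambda must be positive")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class BaselineResult:
    F0: np.ndarray  # (T, H, W), strictly positive
    dFF: np.ndarray  # (T, H, W)
    params_echo: BaselineParams
    converged: bool = True
    floored_mask: np.ndarray | None = None  # (H, W) pixels where the floor engaged


def gaussian_blur_xy(movie: MovieStack, sigma_px: float) -> MovieStack:
    """Frame-wise 2D Gaussian blur; sigma 0 is the identity."""
    if sigma_px < 0:
        raise ConfigError("sigma_px must be >= 0")
    if sigma_px == 0:
        return MovieStack(movie.frames.copy(), movie.frame_rate_hz,
                          movie.pixel_size_um, movie.t0_s)
    blurred = gaussian_filter(
        movie.frames.astype(np.float32), sigma=(0.0, sigma_px, sigma_px),
        mode="nearest",
    )
    return MovieStack(np.clip(blurred, 0.0, None), movie.frame_rate_hz,
                      movie.pixel_size_um, movie.t0_s)


def leaky_cummin(trace: np.ndarray, eta: float) -> np.ndarray:
    """Leaky cumulative minimum along the first axis.

    m_0 = F_0;  m_t = min(F_t, m_{t-1} + eta * (F_t - m_{t-1})).

    The output never exceeds the input and relaxes upward at rate ``eta``
    per frame, so it hugs the lower envelope while tracking slow rises.
    Works on a 1D trace or a (T, ...) stack (per-pixel independently).
    """
    if not (0.0 < eta < 1.0):
        raise ConfigError("eta must be in (0, 1)")
    trace = np.asarray(trace, dtype=float)
    if trace.shape[0] == 0:
        raise DataError("empty trace")
    out = np.empty_like(trace)
    out[0] = trace[0]
    for t in range(1, trace.shape[0]):
        relaxed = out[t - 1] + eta * (trace[t] - out[t - 1])
        out[t] = np.minimum(trace[t], relaxed)
    return out


def smooth_baseline(
    minima: np.ndarray, params: BaselineParams
) -> tuple[np.ndarray, bool]:
    """Iterated {temporal Gaussian lowpass; clip to <= minima} fixed point.

    A plain smooth-then-clip loop is heat flow under an upper obstacle: it
    has no useful fixed point (run forever, everything diffuses down to the
    global minimum). Each pass therefore also pulls the estimate back
    toward the minima trace with weight ``restore_lambda``,

        F0 <- min(minima, (smooth(F0) + lambda * minima) / (1 + lambda)),

    which is a contraction with a unique fixed point: smooth where the
    minima are smooth, clipped through sharp notches, and anchored to the
    minima elsewhere. Returns (F0, converged); always obeys the minima.
    """
    minima = np.asarray(minima, dtype=float)
    if not np.isfinite(minima).all():
        raise DataError("minima contain non-finite values")
    lam = params.restore_lambda
    f0 = minima.copy()
    scale = np.maximum(np.abs(minima).max(), 1e-12)
    for _ in range(params.n_lowpass_iters):
        smoothed = gaussian_filter1d(
            f0, sigma=params.lowpass_sigma_frames, axis=0, mode="nearest"
        )
        new = np.minimum((smoothed + lam * minima) / (1.0 + lam), minima)
        delta = np.abs(new - f0).max() / scale
        f0 = new
        if delta < params.converge_tol:
            return f0, True
    return f0, False


def compute_dff(movie: MovieStack, params: BaselineParams | None = None) -> BaselineResult:
    """Full baseline pipeline: blur -> leaky cummin -> smooth -> dFF."""
    params = params or BaselineParams()
    blurred = gaussian_blur_xy(movie, params.blur_sigma_px)
    f = blurred.frames.astype(float)
    # light temporal smoothing before the running minimum keeps the
    # envelope near the noise floor instead of its extreme excursions
    if params.pre_smooth_sigma_frames > 0:
        f_min_input = gaussian_filter1d(
            f, params.pre_smooth_sigma_frames, axis=0, mode="nearest"
        )
    else:
        f_min_input = f
    minima = leaky_cummin(f_min_input, params.leak_eta)
    f0, converged = smooth_baseline(minima, params)
    floored = f0.min(axis=0) < params.f0_floor
    f0 = np.maximum(f0, params.f0_floor)
    dff = (f - f0) / f0
    return BaselineResult(
        F0=f0, dFF=dff, params_echo=params, converged=converged,
        floored_mask=floored,
    )
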