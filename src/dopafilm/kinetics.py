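"""Per-trace event kinetics: detection, amplitude, FWHM, decay and rise times.

Metrics operate on dFF traces. Two signal-to-noise quantities appear: the
detection gate in ``find_events`` divides peak height by the robust
noise-floor sigma (usable even when transients pile up), while the ``snr``
function implements the measurement definition — peak dF over the standard
deviation of the baseline fluorescence in a pre-event window.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

from .errors import DataError

__all__ = [
    "EventMetrics",
    "TraceSummary",
    "find_events",
    "temporal_fwhm",
    "fit_tau_off",
    "tau_peak",
    "tau_quantile_range",
    "snr",
    "event_frequency",
    "analyze_trace",
]


@dataclass
class EventMetrics:
    t_peak_s: float
    peak_frame: int
    amplitude_dff: float  # fractional dFF at the peak above local baseline
    snr: float
    fwhm_s: float | None = None
    tau_off_s: float | None = None
    tau_off_r2: float | None = None
    tau_peak_s: float | None = None
    reasons: dict = field(default_factory=dict)

    @property
    def amplitude_pct(self) -> float:
        return 100.0 * self.amplitude_dff


@dataclass
class TraceSummary:
    events: list[EventMetrics]
    event_rate_hz: float
    duration_s: float


def _baseline_window(anchor: int, n: int, pre_gap: int = 5, width: int = 50) -> slice | None:
    """Baseline window ending ``pre_gap`` frames before ``anchor``."""
    hi = anchor - pre_gap
    lo = max(0, hi - width)
    if hi - lo < 10:
        return None
    return slice(lo, hi)


def find_events(
    trace_dff: np.ndarray,
    frame_rate_hz: float,
    min_prominence: float = 0.02,
    min_snr: float = 5.0,
) -> list[EventMetrics]:
    """Local maxima gated by prominence and by noise-floor SNR.

    SNR per candidate = (peak - local baseline) / noise sigma. The local
    baseline comes from a window anchored before the peak's rise (its left
    base); the noise sigma is the robust successive-difference estimate,
    which measures the baseline noise floor even when transients pile up
    and leave no signal-free window.
    """
    trace = np.asarray(trace_dff, dtype=float)
    if trace.ndim != 1 or len(trace) < 5:
        raise DataError("trace must be 1D with >= 5 frames")
    peaks, props = find_peaks(trace, prominence=min_prominence)
    diffs = np.abs(np.diff(trace))
    sigma_noise = 1.4826 * float(np.median(diffs)) / np.sqrt(2.0)
    global_base = float(np.percentile(trace, 10))
    events = []
    for p, left_base in zip(peaks, props["left_bases"]):
        # anchor the baseline window before the rise, not the peak: slow
        # rises and piled-up transients otherwise leak into the window
        win = _baseline_window(int(min(left_base + 1, p)), len(trace), pre_gap=1)
        base = float(trace[win].mean()) if win is not None else global_base
        if sigma_noise == 0:
            ev_snr = np.inf if trace[p] > base else 0.0
        else:
            ev_snr = (trace[p] - base) / sigma_noise
        if ev_snr < min_snr:
            continue
        events.append(
            EventMetrics(
                t_peak_s=p / frame_rate_hz,
                peak_frame=int(p),
                amplitude_dff=float(trace[p] - base),
                snr=float(ev_snr),
            )
        )
    events.sort(key=lambda e: e.t_peak_s)
    return events


def temporal_fwhm(
    trace_dff: np.ndarray, event: EventMetrics, frame_rate_hz: float
) -> float | None:
    """Width (s) at half of (peak - local baseline), linearly interpolated.

    Returns None (reason recorded on the event) if either side never
    crosses the half level before the trace ends.
    """
    trace = np.asarray(trace_dff, dtype=float)
    p = event.peak_frame
    base = trace[p] - event.amplitude_dff
    half = base + 0.5 * event.amplitude_dff

    def cross(direction: int) -> float | None:
        i = p
        while 0 <= i + direction < len(trace):
            j = i + direction
            if trace[j] <= half:
                # linear interpolation between i and j
                frac = (trace[i] - half) / (trace[i] - trace[j])
                return i + direction * frac
            i = j
        return None

    left = cross(-1)
    right = cross(+1)
    if left is None or right is None:
        event.reasons["fwhm"] = "half level not crossed on %s side" % (
            "left" if left is None else "right"
        )
        return None
    event.fwhm_s = float((right - left) / frame_rate_hz)
    return event.fwhm_s


def fit_tau_off(
    trace_dff: np.ndarray,
    event: EventMetrics,
    frame_rate_hz: float,
    fit_window_s: float | None = None,
    next_event_frame: int | None = None,
) -> float | None:
    """First-order decay constant from the peak: A*exp(-t/tau) + c.

    The window runs from the peak to min(10x the initial tau guess, the
    next event onset, trace end). Returns None when the fit fails or tau
    leaves (0, 100] s.
    """
    trace = np.asarray(trace_dff, dtype=float)
    p = event.peak_frame
    base = trace[p] - event.amplitude_dff
    # initial guess: time to decay to 1/e of the amplitude
    target = base + event.amplitude_dff / np.e
    below = np.nonzero(trace[p:] <= target)[0]
    tau_guess = (below[0] / frame_rate_hz) if len(below) else 2.0
    tau_guess = min(max(tau_guess, 1.0 / frame_rate_hz), 100.0)
    if fit_window_s is None:
        fit_window_s = 10.0 * tau_guess
    end = min(len(trace), p + int(round(fit_window_s * frame_rate_hz)) + 1)
    if next_event_frame is not None:
        end = min(end, next_event_frame)
    seg = trace[p:end]
    if len(seg) < 5:
        event.reasons["tau_off"] = "fewer than 5 samples in decay window"
        return None
    tt = np.arange(len(seg)) / frame_rate_hz
    try:
        popt, pcov = curve_fit(
            lambda t, a, tau, c: a * np.exp(-t / tau) + c,
            tt,
            seg,
            p0=[event.amplitude_dff, tau_guess, base],
            bounds=([0.0, 1e-3, -np.inf], [np.inf, 100.0, np.inf]),
            maxfev=2000,
        )
    except (RuntimeError, ValueError):
        event.reasons["tau_off"] = "fit did not converge"
        return None
    tau = float(popt[1])
    if not (0.0 < tau < 100.0):
        event.reasons["tau_off"] = f"tau {tau:.3g} outside (0, 100) s"
        return None
    ss_res = float(np.sum((seg - (popt[0] * np.exp(-tt / tau) + popt[2])) ** 2))
    ss_tot = float(np.sum((seg - seg.mean()) ** 2))
    event.tau_off_s = tau
    event.tau_off_r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return tau


def tau_peak(
    trace_dff: np.ndarray,
    event: EventMetrics,
    frame_rate_hz: float,
    smooth_sigma_frames: float = 2.0,
    window_s: float = 3.0,
) -> float | None:
    """Rise time: peak minus the onset located at the maximum of the
    second difference (of the lightly smoothed trace) in a pre-peak window."""
    trace = np.asarray(trace_dff, dtype=float)
    p = event.peak_frame
    lo = max(0, p - int(round(window_s * frame_rate_hz)))
    if p - lo < 3:
        event.reasons["tau_peak"] = "no usable pre-peak window"
        return None
    sm = gaussian_filter1d(trace, smooth_sigma_frames, mode="nearest")
    second = np.diff(sm, n=2)  # second[i] ~ curvature at frame i+1
    seg = second[lo : p - 1]
    if len(seg) == 0:
        event.reasons["tau_peak"] = "no usable pre-peak window"
        return None
    onset = lo + 1 + int(np.argmax(seg))
    event.tau_peak_s = float(max(p - onset, 0) / frame_rate_hz)
    return event.tau_peak_s


def tau_quantile_range(tau_list) -> float | None:
    """tau_10/90: spread of decay constants, Q(0.9) - Q(0.1) with
    linear-interpolation quantiles. None for fewer than 10 values."""
    taus = np.asarray([t for t in tau_list if t is not None], dtype=float)
    if len(taus) < 10:
        return None
    q10, q90 = np.quantile(taus, [0.1, 0.9])
    return float(q90 - q10)


def snr(
    trace_raw_f: np.ndarray, peak_frame: int, baseline_window: slice | None = None
) -> float:
    """Measurement SNR: (F_peak - mean baseline F) / SD of baseline F."""
    trace = np.asarray(trace_raw_f, dtype=float)
    if baseline_window is None:
        baseline_window = _baseline_window(peak_frame, len(trace))
    if baseline_window is None:
        raise DataError("need >= 10 pre-event baseline frames")
    base = trace[baseline_window]
    if len(base) < 10:
        raise DataError("baseline window must hold >= 10 frames")
    sd = float(base.std(ddof=1))
    df = float(trace[peak_frame] - base.mean())
    if sd == 0:
        return np.inf if df > 0 else 0.0
    return df / sd


def event_frequency(n_events: int, duration_s: float) -> float:
    if duration_s <= 0:
        raise DataError("duration must be positive")
    return n_events / duration_s


def analyze_trace(
    trace_dff: np.ndarray,
    frame_rate_hz: float,
    min_prominence: float = 0.02,
    min_snr: float = 5.0,
) -> TraceSummary:
    """Detect events on one trace and fill in all per-event kinetics."""
    events = find_events(trace_dff, frame_rate_hz, min_prominence, min_snr)
    for i, ev in enumerate(events):
        nxt = events[i + 1].peak_frame if i + 1 < len(events) else None
        temporal_fwhm(trace_dff, ev, frame_rate_hz)
        fit_tau_off(trace_dff, ev, frame_rate_hz, next_event_frame=nxt)
        tau_peak(trace_dff, ev, frame_rate_hz)
    duration = len(np.asarray(trace_dff)) / frame_rate_hz
    return TraceSummary(
        events=events,
        event_rate_hz=event_frequency(len(events), duration),
        duration_s=duration,
    )
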