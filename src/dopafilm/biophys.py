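"""Diffusivity from hotspot broadening; sensor dose-response calibration.

A point-source release spreading in 2D has a Gaussian footprint whose
per-axis variance grows as sigma^2(t) = sigma_0^2 + 2 D t, with sigma_0^2
absorbing the instrument/film point-spread width. Fitting an isotropic
Gaussian to the dF frame around one event per frame and regressing
sigma^2 on time therefore estimates D as slope/2. The film's equilibrium
dose-response follows a Langmuir isotherm dFF = A_max * C / (C + Kd).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit
from scipy.stats import linregress

from ._utils import fit_gaussian_2d
from .errors import DataError, FitError

__all__ = [
    "DiffusionEstimate",
    "CalibrationFit",
    "estimate_variance_series",
    "fit_diffusivity",
    "langmuir_response",
    "fit_calibration",
]

UM2_PER_CM2 = 1e8


@dataclass
class DiffusionEstimate:
    times_s: np.ndarray
    sigma2_um2: np.ndarray
    D_um2_s: float
    intercept_um2: float
    r2: float
    clipped_to_zero: bool = False

    @property
    def D_cm2_s(self) -> float:
        return self.D_um2_s / UM2_PER_CM2


@dataclass
class CalibrationFit:
    Kd_nM: float
    A_max: float
    Kd_ci95_nM: tuple[float, float]
    A_max_ci95: tuple[float, float]
    residuals: np.ndarray
    dose_response: list[tuple[float, float]] = field(default_factory=list)
    ill_conditioned: bool = False


def estimate_variance_series(
    dff_frames: np.ndarray,
    centroid_px: tuple[float, float],
    times_s: np.ndarray,
    pixel_size_um: float,
    min_amplitude_snr: float = 3.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-frame isotropic Gaussian variance (um^2) about a fixed centroid.

    Frames whose fit fails or whose fitted amplitude falls below
    ``min_amplitude_snr`` times the frame's robust noise are dropped.
    Returns (times, sigma^2); raises if fewer than 3 frames survive.
    """
    frames = np.asarray(dff_frames, dtype=float)
    times_s = np.asarray(times_s, dtype=float)
    if frames.ndim != 3 or len(times_s) != frames.shape[0]:
        raise DataError("need (T, H, W) frames with matching times")
    out_t, out_s2 = [], []
    for frame, t in zip(frames, times_s):
        noise = 1.4826 * np.median(np.abs(frame - np.median(frame)))
        fit = fit_gaussian_2d(frame, center_px=centroid_px, fix_center=True)
        if not fit.success or fit.amplitude <= 0:
            continue
        if noise > 0 and fit.amplitude < min_amplitude_snr * noise:
            continue
        out_t.append(t)
        out_s2.append((fit.sigma_px * pixel_size_um) ** 2)
    if len(out_t) < 3:
        raise FitError("fewer than 3 usable frames for the variance series")
    return np.asarray(out_t), np.asarray(out_s2)


def fit_diffusivity(times_s: np.ndarray, sigma2_um2: np.ndarray) -> DiffusionEstimate:
    """Least-squares line sigma^2(t) = sigma_0^2 + 2 D t; D = slope / 2.

    A negative slope is clipped to D = 0 and flagged.
    """
    times_s = np.asarray(times_s, dtype=float)
    sigma2_um2 = np.asarray(sigma2_um2, dtype=float)
    if len(times_s) < 3:
        raise DataError("variance series needs >= 3 points")
    res = linregress(times_s, sigma2_um2)
    slope = float(res.slope)
    clipped = slope < 0
    d = max(slope, 0.0) / 2.0
    return DiffusionEstimate(
        times_s=times_s,
        sigma2_um2=sigma2_um2,
        D_um2_s=d,
        intercept_um2=float(res.intercept),
        r2=float(res.rvalue**2),
        clipped_to_zero=clipped,
    )


def langmuir_response(conc_nM, Kd_nM: float, A_max: float):
    """Equilibrium turn-on isotherm dFF = A_max * C / (C + Kd)."""
    conc = np.asarray(conc_nM, dtype=float)
    if np.any(conc < 0):
        raise DataError("concentrations must be >= 0")
    return A_max * conc / (conc + Kd_nM)


def fit_calibration(dose_response) -> CalibrationFit:
    """Nonlinear least squares for (Kd, A_max) from (conc_nM, dFF) pairs.

    Requires >= 4 concentrations spanning >= 2 decades. The fit is flagged
    ill-conditioned when the covariance leaves Kd effectively unbounded
    (all points in the linear regime make Kd and A_max unidentifiable
    separately).
    """
    pairs = np.asarray(list(dose_response), dtype=float)
    if pairs.ndim != 2 or pairs.shape[1] != 2 or pairs.shape[0] < 4:
        raise DataError("need >= 4 (concentration, dFF) pairs")
    conc, dff = pairs[:, 0], pairs[:, 1]
    if np.any(conc <= 0):
        raise DataError("concentrations must be positive")
    if np.log10(conc.max() / conc.min()) < 2:
        raise DataError("concentrations must span >= 2 decades")
    kd0 = float(np.interp(dff.max() / 2.0, dff, conc))
    p0 = [max(kd0, conc.min()), float(dff.max())]
    try:
        popt, pcov = curve_fit(
            langmuir_response, conc, dff, p0=p0,
            bounds=([1e-9, 1e-12], [np.inf, np.inf]), maxfev=5000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitError(
            "calibration fit did not converge; try an initial Kd near the "
            "half-saturating concentration"
        ) from exc
    kd, amax = float(popt[0]), float(popt[1])
    perr = np.sqrt(np.clip(np.diag(pcov), 0, None))
    ill = (not np.isfinite(perr).all()) or perr[0] > 0.5 * kd or kd > 2 * conc.max()
    return CalibrationFit(
        Kd_nM=kd,
        A_max=amax,
        Kd_ci95_nM=(kd - 1.96 * perr[0], kd + 1.96 * perr[0]),
        A_max_ci95=(amax - 1.96 * perr[1], amax + 1.96 * perr[1]),
        residuals=dff - langmuir_response(conc, kd, amax),
        dose_response=[(float(c), float(v)) for c, v in pairs],
        ill_conditioned=bool(ill),
    )
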