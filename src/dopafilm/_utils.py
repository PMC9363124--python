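"""Shared numerical helpers: seeding, 2D Gaussian fitting."""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

# FWHM of a Gaussian = 2*sqrt(2*ln 2) * sigma
FWHM_PER_SIGMA = 2.0 * np.sqrt(2.0 * np.log(2.0))


def derive_seed(master_seed: int, stage: str) -> int:
    """Derive a stable per-stage seed from a master seed and a stage name.

    Uses blake2b so there is no hidden global randomness and derived seeds
    stay below 2**31.
    """
    digest = hashlib.blake2b(f"{int(master_seed)}:{stage}".encode(), digest_size=8)
    return int.from_bytes(digest.digest(), "little") % (2**31)


@dataclass
class Gaussian2DFit:
    amplitude: float
    x0_px: float
    y0_px: float
    sigma_px: float
    offset: float
    success: bool
    reason: str = ""

    @property
    def fwhm_px(self) -> float:
        return FWHM_PER_SIGMA * self.sigma_px


def _iso_gauss(coords, amplitude, x0, y0, sigma, offset):
    x, y = coords
    r2 = (x - x0) ** 2 + (y - y0) ** 2
    return amplitude * np.exp(-r2 / (2.0 * sigma**2)) + offset


def fit_gaussian_2d(
    image: np.ndarray,
    center_px: tuple[float, float] | None = None,
    fix_center: bool = False,
    sigma_guess_px: float | None = None,
) -> Gaussian2DFit:
    """Least-squares fit of an isotropic 2D Gaussian (+ constant offset).

    Parameters
    ----------
    image
        2D array (rows = y, cols = x).
    center_px
        Optional (x, y) initial center in pixel units. Defaults to the
        intensity-weighted centroid of the positive part of the image.
    fix_center
        If True the center is held fixed at ``center_px`` and only
        (amplitude, sigma, offset) are fitted.
    """
    img = np.asarray(image, dtype=float)
    h, w = img.shape
    yy, xx = np.mgrid[0:h, 0:w]
    x = xx.ravel().astype(float)
    y = yy.ravel().astype(float)
    z = img.ravel()

    pos = np.clip(z - np.median(z), 0, None)
    if center_px is None:
        tot = pos.sum()
        if tot <= 0:
            return Gaussian2DFit(0.0, w / 2, h / 2, 1.0, 0.0, False, "no positive signal")
        center_px = (float((x * pos).sum() / tot), float((y * pos).sum() / tot))
    x0g, y0g = center_px

    amp_g = float(z.max() - np.median(z))
    if amp_g <= 0:
        return Gaussian2DFit(0.0, x0g, y0g, 1.0, float(z.mean()), False, "flat image")
    if sigma_guess_px is None:
        tot = pos.sum()
        if tot > 0:
            var = ((x - x0g) ** 2 + (y - y0g) ** 2) * pos
            sigma_guess_px = float(np.sqrt(max(var.sum() / tot / 2.0, 0.25)))
        else:
            sigma_guess_px = 1.0
    off_g = float(np.median(z))

    try:
        if fix_center:
            def model(coords, amplitude, sigma, offset):
                return _iso_gauss(coords, amplitude, x0g, y0g, sigma, offset)

            p0 = [amp_g, sigma_guess_px, off_g]
            bounds = ([0.0, 1e-3, -np.inf], [np.inf, max(h, w) * 2.0, np.inf])
            popt, _ = curve_fit(model, (x, y), z, p0=p0, bounds=bounds, maxfev=2000)
            return Gaussian2DFit(popt[0], x0g, y0g, popt[1], popt[2], True)
        p0 = [amp_g, x0g, y0g, sigma_guess_px, off_g]
        bounds = (
            [0.0, -1.0, -1.0, 1e-3, -np.inf],
            [np.inf, w + 1.0, h + 1.0, max(h, w) * 2.0, np.inf],
        )
        popt, _ = curve_fit(_iso_gauss, (x, y), z, p0=p0, bounds=bounds, maxfev=2000)
        return Gaussian2DFit(popt[0], popt[1], popt[2], popt[3], popt[4], True)
    except (RuntimeError, ValueError) as exc:  # pragma: no cover - rare fit failure
        return Gaussian2DFit(amp_g, x0g, y0g, sigma_guess_px, off_g, False, str(exc))


def radial_half_max_radius_px(
    frame: np.ndarray,
    center_px: tuple[float, float],
    max_radius_px: int = 40,
    bg_annulus_px: tuple[int, int] = (10, 14),
) -> float:
    """Radius (px) where the azimuthal mean profile falls to half max.

    Background is taken from a local annulus (default 10-14 px out), so a
    smooth ambient field — neighboring sites' spillover, residual baseline
    offset — does not inflate the half-max radius. The peak is the
    innermost annulus mean. Returns ``max_radius_px`` if the half level is
    never crossed.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.hypot(xx - center_px[0], yy - center_px[1])
    prof = []
    for i in range(max_radius_px):
        ring = frame[(r >= i) & (r < i + 1)]
        prof.append(float(ring.mean()) if ring.size else np.nan)
    ring_bg = frame[(r >= bg_annulus_px[0]) & (r < bg_annulus_px[1])]
    bg = float(np.median(ring_bg)) if ring_bg.size else float(np.median(frame))
    peak = prof[0]
    half = bg + 0.5 * (peak - bg)
    for i in range(1, max_radius_px):
        if np.isnan(prof[i]):
            continue
        if prof[i] <= half:
            lo, hi = prof[i - 1], prof[i]
            frac = (lo - half) / (lo - hi) if lo != hi else 0.5
            return (i - 1) + frac + 0.5  # annulus centers at i + 0.5
    return float(max_radius_px)


def fit_blob_fwhm(
    frame: np.ndarray,
    center_px: tuple[float, float],
    min_halfwidth_px: int = 6,
    max_halfwidth_px: int = 40,
) -> Gaussian2DFit:
    """Gaussian FWHM of one blob, windowed by a direct half-max radius.

    For heavy-tailed profiles the fitted Gaussian width depends on how much
    tail the window admits, so the window is defined by the data itself:
    halfwidth = 3x the radial half-max radius. Everyone measuring a width
    (the simulator planting one, the hotspot stage recovering one) crops
    identically by construction.
    """
    frame = np.asarray(frame, dtype=float)
    h, w = frame.shape
    cx, cy = center_px
    r_half = radial_half_max_radius_px(frame, center_px)
    halfwidth = int(np.clip(np.ceil(3.0 * r_half), min_halfwidth_px, max_halfwidth_px))
    x0 = int(max(0, round(cx) - halfwidth))
    x1 = int(min(w, round(cx) + halfwidth + 1))
    y0 = int(max(0, round(cy) - halfwidth))
    y1 = int(min(h, round(cy) + halfwidth + 1))
    fit = fit_gaussian_2d(frame[y0:y1, x0:x1], center_px=(cx - x0, cy - y0))
    fit.x0_px += x0
    fit.y0_px += y0
    return fit
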