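"""Fixture-recovery analyses on the synthetic presets.

Each routine simulates a preset with known ground truth, runs the full
detection pipeline on the rendered movie, and measures how well a planted
quantity is recovered. Used by the validation test suite and the
stand-alone recovery script.
"""

from __future__ import annotations

import numpy as np

from ._utils import derive_seed
from .biophys import estimate_variance_series, fit_calibration, fit_diffusivity, langmuir_response
from .hotspots import detect_varicosities, hotspot_spacing, match_hotspots
from .pipeline import detect_hotspots_in_movie
from .simcore import generate_dataset, get_preset, render_structural_image

__all__ = [
    "axon_localization_repeats",
    "dendrite_recovery",
    "diffusivity_recovery",
    "calibration_recovery",
]


def axon_localization_repeats(
    n_repeats: int = 5,
    seed: int = 1,
    n_release: int = 10,
    n_varicosities: int = 31,
    match_radius_um: float = 1.7,
) -> dict:
    """Repeat-evoked localization: hotspot centroids vs true release sites.

    Simulates ``n_repeats`` evoked movies of the same axonal arbor (same
    geometry, independent release/noise realizations), matches detected
    hotspots to the ground-truth release-site positions per repeat, then
    averages each site's matched centroids across repeats. Returns per-site
    offsets of the repeat-averaged centroid and their maximum (um).
    """
    per_site: dict[int, list[tuple[float, float]]] = {}
    sites = None
    for r in range(n_repeats):
        rep_seed = derive_seed(seed, f"axon-repeat-{r}")
        cfg, schedule = get_preset(
            "evoked_axon", seed=rep_seed,
            n_release=n_release, n_varicosities=n_varicosities,
        )
        movie, truth = generate_dataset(cfg, schedule, seed=rep_seed)
        if sites is None:
            sites = [
                p for p, c in zip(truth.site_positions_um, truth.site_competent) if c
            ]
        _, hotspots = detect_hotspots_in_movie(movie)
        centroids = [h.centroid_um for h in hotspots if h.centroid_um is not None]
        matches = match_hotspots(centroids, sites, max_radius_um=match_radius_um)
        for m in matches["matches"]:
            per_site.setdefault(m["varicosity"], []).append(centroids[m["hotspot"]])

    offsets = {}
    for site_idx, cents in per_site.items():
        mean_c = np.mean(np.asarray(cents), axis=0)
        tx, ty = sites[site_idx]
        offsets[site_idx] = float(np.hypot(mean_c[0] - tx, mean_c[1] - ty))
    return {
        "n_sites": len(sites),
        "n_matched_sites": len(offsets),
        "offsets_um": offsets,
        "max_offset_um": max(offsets.values()) if offsets else float("nan"),
    }


def dendrite_recovery(n_seeds: int = 10, seed: int = 1) -> dict:
    """Dendritic fixture: spacing, spatial FWHM and competent fraction.

    For each seed, simulates the dendrite preset (10 release sites planted
    every 7.5 um along a 75 um path, hotspot spread planted at 3.2 um,
    10 of 30 varicosities competent), runs detection, and measures the
    along-path spacing, the per-hotspot spatial FWHM, and the matched
    fraction of varicosities.
    """
    spacing_means, fwhms, fractions = [], [], []
    planted_fraction = None
    n_varic = None
    for r in range(n_seeds):
        rep_seed = derive_seed(seed, f"dendrite-{r}")
        cfg, schedule = get_preset("dendrite", seed=rep_seed)
        movie, truth = generate_dataset(cfg, schedule, seed=rep_seed)
        planted_fraction = truth.competent_fraction
        _, hotspots = detect_hotspots_in_movie(movie)
        centroids = [h.centroid_um for h in hotspots if h.centroid_um is not None]
        sp = hotspot_spacing(centroids, truth.dendrite_path_um)
        if sp["mean_um"] is not None:
            spacing_means.append(sp["mean_um"])
        fwhms.extend(h.spatial_fwhm_um for h in hotspots if h.spatial_fwhm_um)
        structural, mask = render_structural_image(schedule, cfg)
        varic = detect_varicosities(structural, mask, cfg.pixel_size_um)
        n_varic = len(varic.centroids_um)
        matched = match_hotspots(centroids, varic.centroids_um, max_radius_um=1.7)
        fractions.append(matched["competent_fraction"])
    return {
        "spacing_mean_um": float(np.mean(spacing_means)),
        "spacing_per_seed_um": spacing_means,
        "fwhm_mean_um": float(np.mean(fwhms)),
        "fwhm_values_um": fwhms,
        "competent_fraction_mean": float(np.mean(fractions)),
        "planted_fraction": planted_fraction,
        "n_varicosities": n_varic,
    }


def diffusivity_recovery(seed: int = 1, n_frames: int = 8) -> dict:
    """Noiseless point-source fixture: D from Gaussian-variance regression.

    The fixture movie has no drift, so dF is taken against the pre-event
    mean frame (the envelope baseline is for long drifting recordings).
    """
    cfg, schedule = get_preset("diffusion_fixture", seed=seed)
    movie, truth = generate_dataset(cfg, schedule, seed=seed)
    ev = truth.events[0]
    fr = cfg.frame_rate_hz
    pk = int(np.ceil(ev.time_s * fr))
    f = movie.frames.astype(float)
    df = f - f[:pk].mean(axis=0)
    times = (np.arange(pk + 1, pk + 1 + n_frames) / fr) - ev.time_s
    tt, s2 = estimate_variance_series(
        df[pk + 1 : pk + 1 + n_frames],
        (ev.x_um / cfg.pixel_size_um, ev.y_um / cfg.pixel_size_um),
        times,
        cfg.pixel_size_um,
    )
    est = fit_diffusivity(tt, s2)
    return {
        "D_true_um2_s": cfg.D_um2_s,
        "D_um2_s": est.D_um2_s,
        "D_cm2_s": est.D_cm2_s,
        "r2": est.r2,
        "n_frames": len(tt),
    }


def calibration_recovery(
    kd_nM: float = 268.0, a_max: float = 1.0, n_points: int = 12
) -> dict:
    """Noiseless log-spaced dose-response (1 nM .. 100 uM) -> fitted Kd."""
    conc = np.logspace(0, 5, n_points)
    dff = langmuir_response(conc, kd_nM, a_max)
    fit = fit_calibration(list(zip(conc, dff)))
    return {
        "Kd_true_nM": kd_nM,
        "Kd_nM": fit.Kd_nM,
        "A_max": fit.A_max,
        "n_points": n_points,
        "ill_conditioned": fit.ill_conditioned,
    }
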