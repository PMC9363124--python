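"""Hotspot segmentation of the dF stack and spatial statistics.

The dF stack (negatives clipped) is factorized as X ~ W H with W >= 0 the
per-component spatial maps (pixels x k) and H >= 0 the temporal loadings
(k x T), minimizing

    ||X - W H||_F^2  +  alpha * ||W||_1  +  beta * tr(W^T L W)

where L is the 4-neighbor graph Laplacian of the pixel grid. The L1 term
sparsifies maps; the Laplacian term penalizes spatially rough maps, the
"contiguity" constraint. Multiplicative updates keep the objective
non-increasing. Each component is then reduced to a pixel cluster (pixels
above a fraction of the map's max, largest connected region), a dFF trace,
an intensity-weighted centroid, and a Gaussian spatial FWHM.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import scipy.sparse as sp
from skimage.measure import label, regionprops

from ._utils import derive_seed, fit_blob_fwhm
from .errors import ConfigError, DataError
from .baseline import BaselineResult

__all__ = [
    "NnmfParams",
    "Hotspot",
    "VaricositySet",
    "nnmf_decompose",
    "component_trace",
    "centroid",
    "spatial_fwhm",
    "detect_varicosities",
    "match_hotspots",
    "hotspot_spacing",
    "trace_snr",
    "filter_hotspots_by_snr",
]


@dataclass(frozen=True)
class NnmfParams:
    k: int | str = "auto"
    k_max: int = 20
    alpha_sparsity: float = 0.0
    beta_contiguity: float = 0.1
    max_iter: int = 150
    tol: float = 1e-4  # relative objective change per iteration
    n_restarts: int = 2
    seed: int = 0
    cluster_frac: float = 0.3
    split_blobs: bool = True  # one hotspot per connected blob of a map
    min_blob_px: int = 20  # fragments below a resolvable core area are noise
    max_split_blobs: int = 12  # a map shattering into more blobs is noise
    center: str = "median"  # per-pixel temporal re-zeroing before clipping
    detect_snr: float = 5.0  # an added rank must itself be a detectable signal
    rel_gain_floor: float = 1e-3  # of total energy; guards degenerate growth

    def __post_init__(self):
        if self.alpha_sparsity < 0 or self.beta_contiguity < 0:
            raise ConfigError("penalty weights must be >= 0")
        if not (0.0 < self.cluster_frac < 1.0):
            raise ConfigError("cluster_frac must be in (0, 1)")
        if self.k != "auto" and (not isinstance(self.k, int) or self.k < 1):
            raise ConfigError("k must be a positive integer or 'auto'")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class Hotspot:
    component_index: int
    spatial_map: np.ndarray  # (H, W), max-normalized
    loading: np.ndarray  # (T,) temporal loading from the factorization
    pixel_cluster: np.ndarray  # (H, W) bool
    pixel_size_um: float
    trace_dff: np.ndarray | None = None
    centroid_um: tuple[float, float] | None = None
    spatial_fwhm_um: float | None = None
    fwhm_reason: str = ""
    flags: list[str] = field(default_factory=list)

    @property
    def peak_frame(self) -> int:
        ref = self.trace_dff if self.trace_dff is not None else self.loading
        return int(np.argmax(ref))


@dataclass
class VaricositySet:
    centroids_um: list[tuple[float, float]]
    intensity_threshold_used: float  # multiples of the along-process mean
    source_image_id: str = ""


# --------------------------------------------------------------------------
# NNMF
# --------------------------------------------------------------------------


def _grid_adjacency(h: int, w: int) -> sp.csr_matrix:
    """4-neighbor adjacency of an h x w pixel grid (pixels flattened C-order)."""
    return sp.csr_matrix(
        sp.kron(sp.identity(h), _path_adj(w)) + sp.kron(_path_adj(h), sp.identity(w))
    )


def _path_adj(n: int) -> sp.csr_matrix:
    d = np.ones(n - 1)
    return sp.diags([d, d], [-1, 1], format="csr")


def nnmf_objective(
    x: np.ndarray, w: np.ndarray, h: np.ndarray, alpha: float, beta: float,
    adj: sp.csr_matrix, deg: np.ndarray,
) -> float:
    resid = x - w @ h
    rough = float(
        np.sum(deg[:, None] * w * w, dtype=np.float64)
        - np.sum(w * (adj @ w), dtype=np.float64)
    )
    return (
        float(np.sum(resid * resid, dtype=np.float64))
        + alpha * float(np.sum(w, dtype=np.float64))
        + beta * rough
    )


def _residual_init(
    x: np.ndarray,
    warm: tuple[np.ndarray, np.ndarray] | None,
    grid_shape: tuple[int, int],
) -> tuple[np.ndarray, np.ndarray]:
    """Matched-filter seed for one new component from the positive residual.

    The seed pixel maximizes the residual energy after temporal boxcar
    smoothing (transients span many frames; white noise does not) and 3x3
    spatial smoothing (a single hot noise pixel cannot outvote a spatially
    coherent unexplained site). The seed trace averages the residual over
    that neighborhood.
    """
    from scipy.ndimage import uniform_filter, uniform_filter1d

    r = x if warm is None else np.clip(x - warm[0] @ warm[1], 0.0, None)
    rs = uniform_filter1d(r, size=5, axis=1, mode="nearest")
    energy = np.einsum("pt,pt->p", rs, rs).reshape(grid_shape)
    p_star = int(np.argmax(uniform_filter(energy, size=3, mode="constant")))
    iy, ix = divmod(p_star, grid_shape[1])
    ys = slice(max(0, iy - 1), min(grid_shape[0], iy + 2))
    xs = slice(max(0, ix - 1), min(grid_shape[1], ix + 2))
    neighborhood = (
        np.zeros(grid_shape, dtype=bool)
    )
    neighborhood[ys, xs] = True
    h_new = r[neighborhood.ravel()].mean(axis=0)
    denom = float(h_new @ h_new) + 1e-12
    w_new = r @ h_new / denom
    floor = 1e-6 * max(float(w_new.max()), 1e-12)
    return np.maximum(w_new, floor), np.maximum(h_new, 1e-6 * max(float(h_new.max()), 1e-12))


def _nnmf_single(
    x: np.ndarray, k: int, params: NnmfParams, adj: sp.csr_matrix, deg: np.ndarray,
    rng: np.random.Generator | None,
    warm: tuple[np.ndarray, np.ndarray] | None = None,
    grid_shape: tuple[int, int] | None = None,
) -> tuple[np.ndarray, np.ndarray, list[float], bool]:
    """One multiplicative-update run; returns (W, H, objective path, converged).

    ``warm`` seeds the first k-1 components from a lower-rank solution; the
    added component is matched-filter-initialized from the residual when
    ``rng`` is None (requires ``grid_shape``), otherwise randomized.
    """
    p, t = x.shape
    scale = np.sqrt(x.mean() / max(k, 1))
    if rng is None:
        w = np.empty((p, k), dtype=x.dtype)
        h = np.empty((k, t), dtype=x.dtype)
        w[:, -1], h[-1] = _residual_init(x, warm, grid_shape)
    else:
        w = (rng.uniform(0.2, 1.0, size=(p, k)) * scale).astype(x.dtype)
        h = (rng.uniform(0.2, 1.0, size=(k, t)) * scale).astype(x.dtype)
    if warm is not None:
        w_prev, h_prev = warm
        w[:, : w_prev.shape[1]] = w_prev
        h[: h_prev.shape[0]] = h_prev
    eps = 1e-12
    alpha, beta = params.alpha_sparsity, params.beta_contiguity
    objs = [nnmf_objective(x, w, h, alpha, beta, adj, deg)]
    converged = False
    for _ in range(params.max_iter):
        # H update (no penalties on H)
        wtx = w.T @ x
        wtwh = (w.T @ w) @ h
        h *= wtx / (wtwh + eps)
        # W update with L1 (alpha) and graph-Laplacian (beta) penalties
        xht = x @ h.T
        whht = w @ (h @ h.T)
        num = xht + beta * (adj @ w)
        den = whht + 0.5 * alpha + beta * (deg[:, None] * w)
        w *= num / (den + eps)
        objs.append(nnmf_objective(x, w, h, alpha, beta, adj, deg))
        if abs(objs[-2] - objs[-1]) <= params.tol * max(objs[-2], eps):
            converged = True
            break
    return w, h, objs, converged


def _fit_rank(
    x: np.ndarray, k: int, params: NnmfParams, adj, deg, base_seed: int
) -> tuple[np.ndarray, np.ndarray, float, bool]:
    best = None
    for r in range(params.n_restarts):
        rng = np.random.default_rng(derive_seed(base_seed, f"nnmf-k{k}-r{r}"))
        w, h, objs, conv = _nnmf_single(x, k, params, adj, deg, rng)
        if best is None or objs[-1] < best[2]:
            best = (w, h, objs[-1], conv)
    return best


def nnmf_decompose(
    dff_stack: np.ndarray,
    params: NnmfParams | None = None,
    pixel_size_um: float = 1.0,
) -> list[Hotspot]:
    """Factorize a (T, H, W) dF or dFF stack into hotspot components.

    By default each pixel's trace is first re-zeroed at its temporal median
    (removes the small positive offset a lower-envelope baseline leaves in
    dF); remaining negative values (noise by construction) are clipped to
    zero. Clipping gives the noise a positive mean, so on noisy movies one
    component typically becomes a spatially flat background — its flat
    trace fails any downstream SNR gate.

    With ``k="auto"`` the rank grows one warm-started component at a time
    (the new component is matched-filter-seeded from the residual) and
    stops when the added component is no longer a detectable signal: its
    cluster's data trace must clear ``detect_snr`` and the rank must still
    reduce the reconstruction energy by more than ``rel_gain_floor`` of the
    total. Components are ordered by explained energy.
    """
    params = params or NnmfParams()
    stack = np.asarray(dff_stack, dtype=np.float32)
    if stack.ndim != 3:
        raise DataError("dff_stack must be (T, H, W)")
    if not np.isfinite(stack).all():
        raise DataError("dff_stack contains non-finite values")
    t, hh, ww = stack.shape
    x = stack.reshape(t, hh * ww).T.astype(np.float32)  # pixels x T
    if params.center == "median":
        x = x - np.median(x, axis=1, keepdims=True)
    x = np.clip(x, 0.0, None)
    if x.max() <= 0:
        return []

    adj = _grid_adjacency(hh, ww).astype(np.float32)
    deg = np.asarray(adj.sum(axis=1)).ravel().astype(np.float32)
    err0_sq = float(np.sum(x * x, dtype=np.float64))

    if params.k == "auto":
        prev = None
        err_prev = err0_sq
        for k in range(1, params.k_max + 1):
            warm = (prev[0], prev[1]) if prev is not None else None
            # deterministic matched-filter seed from the residual; the
            # warm start makes random restarts redundant here
            w, h, _, conv = _nnmf_single(
                x, k, params, adj, deg, None, warm=warm, grid_shape=(hh, ww)
            )
            err_k = float(np.sum((x - w @ h) ** 2, dtype=np.float64))
            new_snr = _component_data_snr(x, w[:, -1], params)
            if (
                err_prev - err_k < params.rel_gain_floor * err0_sq
                or new_snr < params.detect_snr
            ):
                if prev is None:
                    return []
                w, h, conv = prev
                break
            prev, err_prev = (w, h, conv), err_k
        else:
            w, h, conv = prev
    else:
        w, h, _, conv = _fit_rank(x, int(params.k), params, adj, deg, params.seed)

    # push scale into H, order components by energy
    norms_w = np.linalg.norm(w, axis=0)
    norms_h = np.linalg.norm(h, axis=1)
    energy = norms_w * norms_h
    order = np.argsort(-energy)
    hotspots: list[Hotspot] = []
    for j in order:
        wmax = w[:, j].max()
        if wmax <= 0 or energy[j] <= 0:
            continue
        smap = (w[:, j] / wmax).reshape(hh, ww)
        loading = h[j] * wmax
        for smap_b, cluster, split in _component_blobs(smap, params):
            hs = Hotspot(
                component_index=len(hotspots),
                spatial_map=smap_b,
                loading=loading,
                pixel_cluster=cluster,
                pixel_size_um=pixel_size_um,
            )
            if split:
                hs.flags.append("split_from_multiblob_component")
            if not conv:
                hs.flags.append("nnmf_not_converged")
            hotspots.append(hs)
    return hotspots


def _component_blobs(smap: np.ndarray, params: NnmfParams):
    """Blobs of one spatial map at the cluster threshold.

    Sites whose activity is strongly correlated in time (e.g. shared
    stimulus trains) can end up lumped in a single component with a
    multi-blob map; with ``split_blobs`` each connected blob above
    ``min_blob_px`` becomes its own hotspot carrying the map masked to the
    blob. Single-blob components keep the full map and the largest
    connected region, yielding (map, cluster, was_split) triples ordered by
    blob energy.
    """
    mask = smap >= params.cluster_frac * smap.max()
    lab = label(mask, connectivity=1)
    n_blobs = int(lab.max())
    if n_blobs <= 1:
        yield smap, mask if n_blobs == 0 else lab == 1, False
        return
    if not params.split_blobs:
        yield smap, _extract_cluster(smap, params.cluster_frac), False
        return
    blobs = []
    for b in range(1, n_blobs + 1):
        blob = lab == b
        if blob.sum() < params.min_blob_px:
            continue
        blobs.append((float(np.sum(smap[blob] ** 2)), b, blob))
    if len(blobs) == 0 or len(blobs) > params.max_split_blobs:
        return  # all fragments tiny, or shattered into dozens: background
    if len(blobs) == 1:
        yield smap, blobs[0][2], False
        return
    blobs.sort(key=lambda t: -t[0])
    for _, b, blob in blobs:
        # mask the map to the blob so centroids and fits see only this site
        yield np.where(blob, smap, 0.0), blob, True


def _component_data_snr(x: np.ndarray, w_col: np.ndarray, params: NnmfParams) -> float:
    """Detection SNR of one component's cluster trace taken from the data."""
    m = float(w_col.max())
    if m <= 0:
        return 0.0
    mask = w_col >= params.cluster_frac * m
    if not mask.any():
        return 0.0
    return trace_snr(x[mask].mean(axis=0))


def _extract_cluster(smap: np.ndarray, frac: float) -> np.ndarray:
    """Pixels >= frac * max(map), restricted to the largest connected region."""
    mask = smap >= frac * smap.max()
    lab = label(mask, connectivity=1)
    if lab.max() == 0:
        return mask
    sizes = np.bincount(lab.ravel())[1:]
    return lab == (1 + int(np.argmax(sizes)))


# --------------------------------------------------------------------------
# per-hotspot statistics
# --------------------------------------------------------------------------


def component_trace(hotspot: Hotspot, baseline: BaselineResult) -> np.ndarray:
    """dFF trace of a hotspot: cluster-mean dF over cluster-mean F0 per frame."""
    mask = hotspot.pixel_cluster
    if not mask.any():
        raise DataError("empty pixel cluster")
    f0 = baseline.F0[:, mask]
    df = baseline.dFF[:, mask] * f0  # back to dF counts
    trace = df.mean(axis=1) / f0.mean(axis=1)
    hotspot.trace_dff = trace
    return trace


def peak_frame_image(
    df_stack: np.ndarray, hotspot: Hotspot, n_avg: int = 5
) -> np.ndarray:
    """Mean dF image over the frames following the hotspot's trace peak.

    After release ends the film's bound-fraction footprint decays nearly
    uniformly in space (unbinding is first-order), so averaging a few
    post-peak frames improves the SNR of centroid and width estimates
    without appreciably broadening the footprint.
    """
    pk = hotspot.peak_frame
    return np.asarray(df_stack[pk : pk + n_avg], dtype=float).mean(axis=0)


def centroid(hotspot: Hotspot, peak_frame_df: np.ndarray) -> tuple[float, float]:
    """Intensity-weighted centroid (x_um, y_um) over the pixel cluster.

    Weights are the dF values at the hotspot's peak frame, clipped at 0;
    falls back to the unweighted cluster centroid if all weights vanish.
    """
    mask = hotspot.pixel_cluster
    if not mask.any():
        raise DataError("empty pixel cluster")
    ys, xs = np.nonzero(mask)
    w = np.clip(np.asarray(peak_frame_df, dtype=float)[ys, xs], 0.0, None)
    if w.sum() <= 0:
        hotspot.flags.append("centroid_unweighted_fallback")
        w = np.ones_like(w)
    cx = float((xs * w).sum() / w.sum()) * hotspot.pixel_size_um
    cy = float((ys * w).sum() / w.sum()) * hotspot.pixel_size_um
    hotspot.centroid_um = (cx, cy)
    return cx, cy


def spatial_fwhm(peak_frame_df: np.ndarray, hotspot: Hotspot) -> float | None:
    """Isotropic-Gaussian FWHM (um) of the hotspot at its peak frame.

    Fits amplitude, center, sigma and offset in a window sized from the
    pixel cluster's area (see ``fit_blob_fwhm``); returns None (with a
    reason on the hotspot) on failure.
    """
    if hotspot.centroid_um is None:
        centroid(hotspot, peak_frame_df)
    px = hotspot.pixel_size_um
    fit = fit_blob_fwhm(
        peak_frame_df,
        (hotspot.centroid_um[0] / px, hotspot.centroid_um[1] / px),
    )
    if not fit.success or fit.amplitude <= 0:
        hotspot.fwhm_reason = fit.reason or "fit failed"
        hotspot.spatial_fwhm_um = None
        return None
    hotspot.spatial_fwhm_um = float(fit.fwhm_px * px)
    return hotspot.spatial_fwhm_um


def deduplicate_hotspots(
    hotspots: list[Hotspot],
    min_separation_um: float = 1.7,
    corr_radius_um: float = 5.0,
    corr_threshold: float = 0.9,
) -> list[Hotspot]:
    """Merge duplicate and spillover hotspots.

    Two mechanisms produce redundant detections: fragmented maps (two
    hotspots within the localization bound ``min_separation_um`` of one
    site) and dopamine spillover (a satellite within ``corr_radius_um``
    whose trace is nearly a copy — correlation above ``corr_threshold`` —
    of a stronger neighbor's). In both cases only the highest-SNR member
    is kept. Distinct sites survive: even stimulus-locked neighbors sit
    farther apart than the correlation radius in any realistic geometry.
    Requires centroids and traces to be filled in already.
    """
    scored = sorted(
        hotspots,
        key=lambda h: -(trace_snr(h.trace_dff) if h.trace_dff is not None else 0.0),
    )
    kept: list[Hotspot] = []
    for h in scored:
        if h.centroid_um is None:
            kept.append(h)
            continue
        dup = False
        for k in kept:
            if k.centroid_um is None:
                continue
            d = np.hypot(
                h.centroid_um[0] - k.centroid_um[0], h.centroid_um[1] - k.centroid_um[1]
            )
            if d < min_separation_um:
                dup = True
                break
            if (
                d < corr_radius_um
                and h.trace_dff is not None
                and k.trace_dff is not None
                and np.corrcoef(h.trace_dff, k.trace_dff)[0, 1] > corr_threshold
            ):
                dup = True
                break
        if not dup:
            kept.append(h)
    kept.sort(key=lambda h: h.component_index)
    return kept


def trace_snr(trace: np.ndarray) -> float:
    """Robust peak SNR of a dFF trace.

    Noise sigma comes from the median absolute successive difference
    (insensitive to slow transients); the baseline is the 10th percentile.
    """
    trace = np.asarray(trace, dtype=float)
    diffs = np.abs(np.diff(trace))
    sigma = 1.4826 * np.median(diffs) / np.sqrt(2.0)
    base = np.percentile(trace, 10)
    if sigma == 0:
        return np.inf if trace.max() > base else 0.0
    return float((trace.max() - base) / sigma)


def filter_hotspots_by_snr(
    hotspots: list[Hotspot],
    baseline: BaselineResult,
    min_snr: float = 5.0,
    max_cluster_area_frac: float = 0.2,
) -> list[Hotspot]:
    """Keep localized hotspots whose cluster dFF trace clears the SNR floor.

    Components whose pixel cluster covers more than
    ``max_cluster_area_frac`` of the field are background (e.g. the flat
    offset clipping leaves in the noise), not hotspots.
    """
    kept = []
    for hs in hotspots:
        if hs.trace_dff is None:
            component_trace(hs, baseline)
        area_frac = hs.pixel_cluster.mean()
        if area_frac > max_cluster_area_frac:
            continue
        if trace_snr(hs.trace_dff) >= min_snr:
            kept.append(hs)
    return kept


# --------------------------------------------------------------------------
# varicosities, matching, spacing
# --------------------------------------------------------------------------


def detect_varicosities(
    structural_image: np.ndarray,
    process_mask: np.ndarray,
    pixel_size_um: float,
    threshold_factor: float = 3.0,
    min_area_px: int = 4,
    source_image_id: str = "",
) -> VaricositySet:
    """Puncta >= threshold_factor x mean along-process intensity.

    Connected regions above threshold with area >= ``min_area_px`` become
    varicosities; centroids are intensity-weighted.
    """
    img = np.asarray(structural_image, dtype=float)
    mask = np.asarray(process_mask, dtype=bool)
    if not mask.any():
        raise DataError("process mask is empty")
    if threshold_factor < 1.0:
        raise ConfigError("threshold_factor must be >= 1")
    mean_intensity = img[mask].mean()
    above = img >= threshold_factor * mean_intensity
    lab = label(above, connectivity=1)
    centroids = []
    for region in regionprops(lab, intensity_image=img):
        if region.area < min_area_px:
            continue
        cy, cx = region.centroid_weighted
        centroids.append((cx * pixel_size_um, cy * pixel_size_um))
    centroids.sort()
    return VaricositySet(
        centroids_um=centroids,
        intensity_threshold_used=threshold_factor,
        source_image_id=source_image_id,
    )


def match_hotspots(
    hotspot_centroids_um: list[tuple[float, float]],
    varicosity_centroids_um: list[tuple[float, float]],
    max_radius_um: float = 1.7,
) -> dict:
    """Greedy nearest-neighbor matching of hotspots to varicosities.

    Pairs are consumed smallest-distance-first without reuse (ties broken
    by lower hotspot index); only pairs within ``max_radius_um`` match.
    competent_fraction = matched varicosities / all varicosities.
    """
    if max_radius_um <= 0:
        raise ConfigError("max_radius_um must be positive")
    hs = np.asarray(hotspot_centroids_um, dtype=float).reshape(-1, 2)
    vs = np.asarray(varicosity_centroids_um, dtype=float).reshape(-1, 2)
    pairs = []
    for i in range(len(hs)):
        for j in range(len(vs)):
            d = float(np.hypot(*(hs[i] - vs[j])))
            if d <= max_radius_um:
                pairs.append((d, i, j))
    pairs.sort()
    used_h, used_v, matches = set(), set(), []
    for d, i, j in pairs:
        if i in used_h or j in used_v:
            continue
        used_h.add(i)
        used_v.add(j)
        matches.append({"hotspot": i, "varicosity": j, "offset_um": d})
    return {
        "matches": matches,
        "unmatched_hotspots": [i for i in range(len(hs)) if i not in used_h],
        "unmatched_varicosities": [j for j in range(len(vs)) if j not in used_v],
        "competent_fraction": (len(used_v) / len(vs)) if len(vs) else float("nan"),
        "offsets_um": [m["offset_um"] for m in matches],
    }


def _project_to_polyline(
    point: np.ndarray, path: np.ndarray
) -> tuple[float, float]:
    """(arclength, lateral distance) of the closest point on a polyline."""
    best = (0.0, np.inf)
    s0 = 0.0
    for a, b in zip(path[:-1], path[1:]):
        ab = b - a
        seg_len = float(np.linalg.norm(ab))
        if seg_len == 0:
            continue
        tproj = np.clip(float((point - a) @ ab) / seg_len**2, 0.0, 1.0)
        nearest = a + tproj * ab
        d = float(np.linalg.norm(point - nearest))
        if d < best[1]:
            best = (s0 + tproj * seg_len, d)
        s0 += seg_len
    return best


def hotspot_spacing(
    centroids_um: list[tuple[float, float]],
    path_polyline_um: list[tuple[float, float]],
    lateral_tol_um: float = 3.0,
) -> dict:
    """Along-path spacing of hotspot centroids via arclength projection.

    Centroids farther than ``lateral_tol_um`` from the path are excluded.
    Returns mean/SD spacing and the spacing list; values are None when
    fewer than two centroids project onto the path.
    """
    path = np.asarray(path_polyline_um, dtype=float)
    arcs = []
    for c in np.asarray(centroids_um, dtype=float).reshape(-1, 2):
        s, d = _project_to_polyline(c, path)
        if d <= lateral_tol_um:
            arcs.append(s)
    arcs.sort()
    if len(arcs) < 2:
        return {"mean_um": None, "sd_um": None, "spacings_um": [], "arclengths_um": arcs}
    spacings = np.diff(arcs)
    return {
        "mean_um": float(spacings.mean()),
        "sd_um": float(spacings.std(ddof=1)) if len(spacings) > 1 else 0.0,
        "spacings_um": [float(s) for s in spacings],
        "arclengths_um": arcs,
    }
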