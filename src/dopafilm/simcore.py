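"""Forward simulation of planar dopamine-film movies with known ground truth.

The physical model, in order of application:

1. Release: vesicular events at fixed sites. Evoked events follow optical
   stimulus trains (5 pulses at 25 Hz by default) with a per-pulse release
   probability; spontaneous events are a per-site Poisson process. Each
   event deposits an instantaneous point mass (one or more quanta,
   lognormally sized) in the 2D plane of the film.
2. Diffusion + clearance: free dopamine spreads by the 2D free-space
   Green's function C(r, t) = Q / (4 pi D t) * exp(-r^2 / (4 D t)), with
   first-order clearance exp(-k_uptake * t) standing in for transporter
   activity.
3. Sensor: the film is a two-state reversible binding surface,
   dS/dt = k_on * C * (1 - S) - k_off * S, with k_on = k_off / Kd so the
   equilibrium isotherm has the measured apparent Kd (268 nM).
4. Camera: expected counts = baseline * (1 + A_max * S); optional Poisson
   shot noise followed by additive Gaussian read noise, clipped at zero.

Coordinates: x runs along columns, y along rows; (0, 0) um is the center of
pixel (row 0, col 0); release sites are snapped to pixel centers.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from functools import lru_cache
from pathlib import Path

import numpy as np
from scipy.special import erf

from ._utils import derive_seed, fit_blob_fwhm
from .errors import ConfigError, DataError, SiteBoundsError

__all__ = [
    "SimulationConfig",
    "StimTrain",
    "QuantaSampler",
    "ReleaseSchedule",
    "Event",
    "GroundTruth",
    "MovieStack",
    "simulate_concentration",
    "apply_sensor",
    "render_movie",
    "sample_events",
    "generate_dataset",
    "render_structural_image",
    "get_preset",
    "PRESET_NAMES",
    "planted_hotspot_fwhm_um",
    "calibrate_release_width_for_fwhm",
]


# --------------------------------------------------------------------------
# configuration and schedule types
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class SimulationConfig:
    """Physical and camera parameters of one simulated experiment.

    Units: um, s, nM, camera counts. ``Q_quantum`` is the 2D mass of one
    vesicle in nM*um^2 (concentration integrated over the plane); its
    default puts a single-quantum response at the few-percent dFF scale of
    measured quantal transients.
    """

    grid_shape: tuple[int, int] = (96, 160)  # (rows, cols)
    pixel_size_um: float = 0.34
    frame_rate_hz: float = 10.0
    duration_s: float = 30.0
    D_um2_s: float = 110.0  # 1.1e-6 cm^2/s
    k_uptake_s: float = 2.0
    sigma_release_um: float = 1.0  # initial extent of the released cloud; 0 = point
    Kd_nM: float = 268.0
    k_off_s: float = 0.26
    A_max: float = 1.0
    Q_quantum: float = 1.5e4
    quantal_cv: float = 0.25
    baseline_counts: float = 2000.0
    read_noise_sd: float = 5.0
    shot_noise: bool = True
    n_substeps: int = 4
    seed: int = 0

    def __post_init__(self):
        if len(self.grid_shape) != 2 or min(self.grid_shape) < 2:
            raise ConfigError(f"grid_shape must be (rows, cols) >= 2, got {self.grid_shape}")
        positive = {
            "pixel_size_um": self.pixel_size_um,
            "frame_rate_hz": self.frame_rate_hz,
            "duration_s": self.duration_s,
            "D_um2_s": self.D_um2_s,
            "Kd_nM": self.Kd_nM,
            "k_off_s": self.k_off_s,
            "A_max": self.A_max,
            "Q_quantum": self.Q_quantum,
            "baseline_counts": self.baseline_counts,
        }
        for name, value in positive.items():
            if not (value > 0) or not math.isfinite(value):
                raise ConfigError(f"{name} must be strictly positive, got {value}")
        if self.k_uptake_s < 0 or not math.isfinite(self.k_uptake_s):
            raise ConfigError("k_uptake_s must be >= 0 (0 disables clearance)")
        if self.sigma_release_um < 0:
            raise ConfigError("sigma_release_um must be >= 0 (0 = point source)")
        if self.quantal_cv < 0:
            raise ConfigError("quantal_cv must be >= 0")
        if self.read_noise_sd < 0:
            raise ConfigError("read_noise_sd must be >= 0")
        if self.n_substeps < 1:
            raise ConfigError("n_substeps must be >= 1")

    @property
    def k_on(self) -> float:
        """Binding rate in nM^-1 s^-1, derived from Kd = k_off / k_on."""
        return self.k_off_s / self.Kd_nM

    @property
    def n_frames(self) -> int:
        return int(round(self.duration_s * self.frame_rate_hz))

    @property
    def extent_um(self) -> tuple[float, float]:
        """(height, width) of the grid in um, pixel-center to pixel-center."""
        h, w = self.grid_shape
        return ((h - 1) * self.pixel_size_um, (w - 1) * self.pixel_size_um)

    def frame_times(self) -> np.ndarray:
        return np.arange(self.n_frames) / self.frame_rate_hz

    def to_dict(self) -> dict:
        d = asdict(self)
        d["grid_shape"] = list(self.grid_shape)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["grid_shape"] = tuple(d["grid_shape"])
        return cls(**d)


@dataclass(frozen=True)
class StimTrain:
    """One optical stimulus train (default: 5 pulses at 25 Hz)."""

    time_s: float
    n_pulses: int = 5
    pulse_rate_hz: float = 25.0
    p_release: float = 0.8

    def pulse_times(self) -> np.ndarray:
        return self.time_s + np.arange(self.n_pulses) / self.pulse_rate_hz


@dataclass(frozen=True)
class QuantaSampler:
    """Sampler spec for the integer number of quanta per event (>= 1).

    kinds: "fixed" (always ``value``), "categorical" (``values`` with
    probabilities ``p``), "poisson_plus_one" (1 + Poisson(``mu``)).
    """

    kind: str = "fixed"
    value: int = 1
    values: tuple[int, ...] = (1, 2, 3)
    p: tuple[float, ...] = (0.7, 0.2, 0.1)
    mu: float = 0.3

    def sample(self, rng: np.random.Generator) -> int:
        if self.kind == "fixed":
            n = self.value
        elif self.kind == "categorical":
            n = int(rng.choice(self.values, p=np.asarray(self.p) / np.sum(self.p)))
        elif self.kind == "poisson_plus_one":
            n = 1 + int(rng.poisson(self.mu))
        else:
            raise ConfigError(f"unknown quanta sampler kind {self.kind!r}")
        if n < 1:
            raise ConfigError("quanta per event must be >= 1")
        return n


@dataclass
class ReleaseSchedule:
    """Sites (competent or not), stimulus trains, and spontaneous rates.

    ``sites`` is a list of (x_um, y_um, is_competent); only competent sites
    release. All sites count as morphological varicosities. Optional
    ``process_paths_um`` carries the polylines of the simulated processes
    (used for the structural image and along-path spacing analyses).
    """

    sites: list[tuple[float, float, bool]]
    evoked: list[StimTrain] = field(default_factory=list)
    spont_rate_hz: float = 0.0
    quanta: QuantaSampler = field(default_factory=QuantaSampler)
    process_paths_um: list[list[tuple[float, float]]] = field(default_factory=list)

    @property
    def competent_indices(self) -> list[int]:
        return [i for i, s in enumerate(self.sites) if s[2]]

    @property
    def competent_fraction(self) -> float:
        return len(self.competent_indices) / len(self.sites)

    def validate_against(self, cfg: SimulationConfig) -> None:
        hy, wx = cfg.extent_um
        for i, (x, y, _) in enumerate(self.sites):
            if not (0.0 <= x <= wx and 0.0 <= y <= hy):
                raise SiteBoundsError(
                    f"site {i} at ({x:.2f}, {y:.2f}) um outside grid extent "
                    f"({wx:.2f} x {hy:.2f} um)"
                )
        for tr in self.evoked:
            if tr.time_s < 0 or tr.pulse_times()[-1] >= cfg.duration_s:
                raise ConfigError(f"stimulus train at {tr.time_s}s runs past the movie")
        if self.spont_rate_hz < 0:
            raise ConfigError("spont_rate_hz must be >= 0")


@dataclass(frozen=True)
class Event:
    """One realized release event (possibly multi-quantal)."""

    site_index: int
    time_s: float
    n_quanta: int
    mass_nM_um2: float
    x_um: float
    y_um: float


@dataclass
class GroundTruth:
    """Simulator truth attached to a generated movie."""

    events: list[Event]
    varicosity_centroids_um: list[tuple[float, float]]
    dendrite_path_um: list[tuple[float, float]] | None
    competent_fraction: float
    config_echo: SimulationConfig
    site_positions_um: list[tuple[float, float]] = field(default_factory=list)
    site_competent: list[bool] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "events": [asdict(e) for e in self.events],
            "varicosity_centroids_um": [list(v) for v in self.varicosity_centroids_um],
            "dendrite_path_um": (
                [list(v) for v in self.dendrite_path_um] if self.dendrite_path_um else None
            ),
            "competent_fraction": self.competent_fraction,
            "config_echo": self.config_echo.to_dict(),
            "site_positions_um": [list(v) for v in self.site_positions_um],
            "site_competent": list(self.site_competent),
        }

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            events=[Event(**e) for e in d["events"]],
            varicosity_centroids_um=[tuple(v) for v in d["varicosity_centroids_um"]],
            dendrite_path_um=(
                [tuple(v) for v in d["dendrite_path_um"]] if d["dendrite_path_um"] else None
            ),
            competent_fraction=d["competent_fraction"],
            config_echo=SimulationConfig.from_dict(d["config_echo"]),
            site_positions_um=[tuple(v) for v in d.get("site_positions_um", [])],
            site_competent=list(d.get("site_competent", [])),
        )

    @classmethod
    def load(cls, path: str | Path) -> "GroundTruth":
        return cls.from_dict(json.loads(Path(path).read_text()))


@dataclass
class MovieStack:
    """Time-ordered stack of nonnegative intensity frames with metadata."""

    frames: np.ndarray  # (T, H, W)
    frame_rate_hz: float
    pixel_size_um: float
    t0_s: float = 0.0

    def __post_init__(self):
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3 or self.frames.shape[0] < 2:
            raise DataError(f"movie must be (T>=2, H, W), got shape {self.frames.shape}")
        if not np.isfinite(self.frames).all():
            raise DataError("movie contains non-finite values")
        if self.frames.min() < 0:
            raise DataError("movie contains negative intensities")
        if self.frame_rate_hz <= 0 or self.pixel_size_um <= 0:
            raise ConfigError("frame_rate_hz and pixel_size_um must be positive")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.frames.shape

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.n_frames) / self.frame_rate_hz


def snap_to_pixel_centers(
    xy_um: tuple[float, float], pixel_size_um: float
) -> tuple[float, float]:
    """Snap a continuous (x, y) um coordinate to the nearest pixel center."""
    return (
        round(xy_um[0] / pixel_size_um) * pixel_size_um,
        round(xy_um[1] / pixel_size_um) * pixel_size_um,
    )


# --------------------------------------------------------------------------
# physics
# --------------------------------------------------------------------------

# exp(-k*dt) below this is treated as fully cleared
_MASS_FLOOR = 1e-8


def _release_age_offset_s(cfg: SimulationConfig) -> float:
    """Virtual age encoding the finite initial cloud: sigma_rel^2 / (2 D).

    A release with Gaussian extent sigma_rel evolves exactly like a point
    source born sigma_rel^2/(2D) earlier, so the finite fusion-cloud width
    is a time offset in the Green's function.
    """
    return cfg.sigma_release_um**2 / (2.0 * cfg.D_um2_s)


def _event_field(
    ev: Event, dt: float, cfg: SimulationConfig, xs: np.ndarray, ys: np.ndarray
) -> np.ndarray | None:
    """Concentration (nM) contributed by one event ``dt`` seconds later."""
    if dt <= 0:
        return None
    decay = math.exp(-cfg.k_uptake_s * dt)
    if decay < _MASS_FLOOR:
        return None
    four_d_dt = 4.0 * cfg.D_um2_s * (dt + _release_age_offset_s(cfg))
    gx = np.exp(-((xs - ev.x_um) ** 2) / four_d_dt)
    gy = np.exp(-((ys - ev.y_um) ** 2) / four_d_dt)
    peak = ev.mass_nM_um2 / (math.pi * four_d_dt) * decay
    return peak * np.outer(gy, gx)


def simulate_concentration(
    events: list[Event], cfg: SimulationConfig, times: np.ndarray
) -> np.ndarray:
    """Free-dopamine concentration stack (nM, T x H x W) at ``times``.

    Superposition over events of the uptake-damped 2D Green's function,
    sampled at pixel centers. Free-space boundaries: no reflection at the
    grid edge, so grids should be sized several diffusion lengths wide.
    """
    times = np.asarray(times, dtype=float)
    if times.ndim != 1 or len(times) < 1:
        raise DataError("times must be a 1D array")
    if len(times) > 1 and not np.all(np.diff(times) > 0):
        raise DataError("times must be strictly increasing")
    if cfg.D_um2_s <= 0:
        raise ConfigError("D_um2_s must be positive")
    hy, wx = cfg.extent_um
    for ev in events:
        if not (0.0 <= ev.x_um <= wx and 0.0 <= ev.y_um <= hy):
            raise SiteBoundsError(
                f"event at ({ev.x_um:.2f}, {ev.y_um:.2f}) um outside the grid"
            )
        if ev.time_s >= times[-1]:
            raise ConfigError(f"event at t={ev.time_s}s is at/after the last sample time")

    h, w = cfg.grid_shape
    xs = np.arange(w) * cfg.pixel_size_um
    ys = np.arange(h) * cfg.pixel_size_um
    conc = np.zeros((len(times), h, w), dtype=float)
    for ev in events:
        for i, t in enumerate(times):
            fld = _event_field(ev, t - ev.time_s, cfg, xs, ys)
            if fld is not None:
                conc[i] += fld
    return conc


def apply_sensor(
    conc: np.ndarray, cfg: SimulationConfig, times: np.ndarray | None = None
) -> np.ndarray:
    """Bound-fraction stack S in [0, 1] from a concentration stack.

    Integrates dS/dt = k_on*C*(1-S) - k_off*S treating C as piecewise
    constant over each sampling interval; the per-interval update is the
    exact solution of the resulting linear ODE, so the scheme is
    unconditionally stable and S stays in [0, 1].
    """
    conc = np.asarray(conc, dtype=float)
    if not np.isfinite(conc).all():
        raise DataError("concentration stack contains non-finite values")
    if conc.min() < -1e-12:
        raise DataError("concentration stack contains negative values")
    n = conc.shape[0]
    if times is None:
        times = np.arange(n) / (cfg.frame_rate_hz * cfg.n_substeps)
    times = np.asarray(times, dtype=float)
    if len(times) != n:
        raise DataError("times length must match the concentration stack")

    out = np.empty_like(conc)
    s = np.zeros(conc.shape[1:], dtype=float)
    dts = np.diff(times)
    dt0 = dts[0] if len(dts) else 1.0 / cfg.frame_rate_hz
    for i in range(n):
        dt = dt0 if i == 0 else dts[i - 1]
        s = _sensor_step(s, conc[i], cfg, dt)
        out[i] = s
    return out


def _sensor_step(
    s: np.ndarray, c: np.ndarray, cfg: SimulationConfig, dt: float
) -> np.ndarray:
    rate = cfg.k_on * c + cfg.k_off_s
    s_inf = cfg.k_on * c / rate
    return s_inf + (s - s_inf) * np.exp(-rate * dt)


def render_movie(
    s_stack: np.ndarray, cfg: SimulationConfig, seed: int | None = None
) -> MovieStack:
    """Camera model: counts = baseline*(1 + A_max*S) with optional noise.

    Identical seed gives a bit-identical movie.
    """
    s_stack = np.asarray(s_stack, dtype=float)
    if s_stack.min() < -1e-9 or s_stack.max() > 1.0 + 1e-9:
        raise DataError("bound fraction must be within [0, 1]")
    if cfg.baseline_counts <= 0:
        raise ConfigError("baseline_counts must be positive")
    expected = cfg.baseline_counts * (1.0 + cfg.A_max * s_stack)
    rng = np.random.default_rng(
        derive_seed(cfg.seed if seed is None else seed, "render")
    )
    frames = rng.poisson(expected).astype(float) if cfg.shot_noise else expected.copy()
    if cfg.read_noise_sd > 0:
        frames = frames + rng.normal(0.0, cfg.read_noise_sd, size=frames.shape)
    frames = np.clip(frames, 0.0, None).astype(np.float32)
    return MovieStack(frames, cfg.frame_rate_hz, cfg.pixel_size_um)


# --------------------------------------------------------------------------
# event sampling and dataset generation
# --------------------------------------------------------------------------


def sample_events(
    schedule: ReleaseSchedule, cfg: SimulationConfig, rng: np.random.Generator
) -> list[Event]:
    """Draw the realized event list (evoked + spontaneous) for one movie."""
    schedule.validate_against(cfg)
    ln_sigma = math.sqrt(math.log(1.0 + cfg.quantal_cv**2))
    ln_mu = math.log(cfg.Q_quantum) - 0.5 * ln_sigma**2

    def quantal_mass(n: int) -> float:
        if cfg.quantal_cv == 0:
            return n * cfg.Q_quantum
        return float(np.sum(rng.lognormal(ln_mu, ln_sigma, size=n)))

    events: list[Event] = []
    for idx in schedule.competent_indices:
        x, y, _ = schedule.sites[idx]
        for train in schedule.evoked:
            for tp in train.pulse_times():
                if rng.uniform() < train.p_release:
                    events.append(Event(idx, float(tp), 1, quantal_mass(1), x, y))
        if schedule.spont_rate_hz > 0:
            n_sp = rng.poisson(schedule.spont_rate_hz * cfg.duration_s)
            for tsp in np.sort(rng.uniform(0.0, cfg.duration_s, size=n_sp)):
                nq = schedule.quanta.sample(rng)
                events.append(Event(idx, float(tsp), nq, quantal_mass(nq), x, y))
    events.sort(key=lambda e: e.time_s)
    return events


def _pixel_integrated_field(
    ev: Event, tau: float, cfg: SimulationConfig, xs: np.ndarray, ys: np.ndarray
) -> np.ndarray:
    """Pixel-area-averaged concentration (nM) ``tau`` seconds post event.

    Separable erf integrals of the free-space Gaussian over each pixel;
    unlike pixel-center sampling this stays finite (mass/pixel-area) as
    tau -> 0, so short-time dose integrals converge.
    """
    px = cfg.pixel_size_um
    s4 = math.sqrt(4.0 * cfg.D_um2_s * (tau + _release_age_offset_s(cfg)))
    gx = 0.5 * (erf((xs - ev.x_um + px / 2) / s4) - erf((xs - ev.x_um - px / 2) / s4))
    gy = 0.5 * (erf((ys - ev.y_um + px / 2) / s4) - erf((ys - ev.y_um - px / 2) / s4))
    return (ev.mass_nM_um2 / px**2) * np.outer(gy, gx)


def _interval_dose(
    ev: Event, tau1: float, tau2: float, cfg: SimulationConfig,
    xs: np.ndarray, ys: np.ndarray,
) -> np.ndarray | None:
    """Time-integrated concentration (nM*s) over [tau1, tau2] post event.

    Midpoint quadrature with geometric refinement across the release
    instant, making the sensor forward model insensitive to the substep
    resolution despite the 1/t singularity of the 2D Green's function.
    """
    if tau2 <= 0:
        return None
    k = cfg.k_uptake_s
    if tau1 <= 1e-12:
        bounds = np.concatenate([[0.0], tau2 * 0.5 ** np.arange(11, -1, -1.0)])
    else:
        bounds = np.linspace(tau1, tau2, 5)
    dose = None
    for a, b in zip(bounds[:-1], bounds[1:]):
        tm = 0.5 * (a + b)
        if tm <= 0:
            continue
        fld = (b - a) * math.exp(-k * tm) * _pixel_integrated_field(ev, tm, cfg, xs, ys)
        dose = fld if dose is None else dose + fld
    return dose


def _event_horizon_s(ev: Event, cfg: SimulationConfig) -> float:
    """Age beyond which an event's remaining peak dose is negligible."""
    tol_nm_s = 0.2  # residual peak dose; Kd is hundreds of nM
    four_pi_d = 4.0 * math.pi * cfg.D_um2_s
    k = cfg.k_uptake_s
    if k <= 0:
        # peak concentration criterion instead (dose diverges logarithmically)
        return ev.mass_nM_um2 / (four_pi_d * 0.05)
    t = 0.1
    while t < 30.0 / k:
        remaining = ev.mass_nM_um2 * math.exp(-k * t) / (four_pi_d * k * t)
        if remaining < tol_nm_s:
            break
        t *= 1.3
    return t


def _integrate_sensor_streaming(
    events: list[Event], cfg: SimulationConfig
) -> np.ndarray:
    """Bound-fraction stack at frame times, integrated on a substep grid.

    Each substep uses the interval-averaged (dose-based) concentration in
    the exact exponential update of the binding ODE. Streams one field at a
    time so long movies never hold a substep-resolution stack in memory.
    """
    h, w = cfg.grid_shape
    xs = np.arange(w) * cfg.pixel_size_um
    ys = np.arange(h) * cfg.pixel_size_um
    n_frames = cfg.n_frames
    nsub = cfg.n_substeps
    dt = 1.0 / (cfg.frame_rate_hz * nsub)

    ev_times = np.array([e.time_s for e in events]) if events else np.empty(0)
    horizons = [_event_horizon_s(e, cfg) for e in events]

    s = np.zeros((h, w), dtype=float)
    out = np.empty((n_frames, h, w), dtype=float)
    out[0] = s  # frame 0 at t=0: nothing released at or before time zero
    for j in range(1, n_frames * nsub):
        t0, t1 = (j - 1) * dt, j * dt
        c = np.zeros((h, w), dtype=float)
        if len(ev_times):
            hi = np.searchsorted(ev_times, t1, side="left")
            for idx in range(hi):
                age = t1 - events[idx].time_s
                if age > horizons[idx]:
                    continue
                dose = _interval_dose(
                    events[idx], t0 - events[idx].time_s, age, cfg, xs, ys
                )
                if dose is not None:
                    c += dose / dt
        s = _sensor_step(s, c, cfg, dt)
        if j % nsub == 0:
            out[j // nsub] = s
    return out


def generate_dataset(
    cfg: SimulationConfig,
    schedule: ReleaseSchedule,
    seed: int | None = None,
    outdir: str | Path | None = None,
) -> tuple[MovieStack, GroundTruth]:
    """Simulate one movie plus its ground truth; optionally write both.

    Writes ``movie.tif`` (with a metadata sidecar) and ``ground_truth.json``
    into ``outdir`` when given. Deterministic for a fixed (cfg, schedule,
    seed).
    """
    master = cfg.seed if seed is None else seed
    rng = np.random.default_rng(derive_seed(master, "events"))
    events = sample_events(schedule, cfg, rng)
    s_stack = _integrate_sensor_streaming(events, cfg)
    movie = render_movie(s_stack, cfg, seed=master)

    truth = GroundTruth(
        events=events,
        varicosity_centroids_um=[(x, y) for x, y, _ in schedule.sites],
        dendrite_path_um=(
            list(schedule.process_paths_um[0]) if schedule.process_paths_um else None
        ),
        competent_fraction=schedule.competent_fraction,
        config_echo=cfg,
        site_positions_um=[(x, y) for x, y, _ in schedule.sites],
        site_competent=[c for _, _, c in schedule.sites],
    )
    if outdir is not None:
        from . import io as dio

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        dio.write_movie_tiff(movie, outdir / "movie.tif")
        truth.save(outdir / "ground_truth.json")
    return movie, truth


# --------------------------------------------------------------------------
# structural channel
# --------------------------------------------------------------------------


def _distance_to_polylines_px(
    shape: tuple[int, int], paths_px: list[np.ndarray]
) -> np.ndarray:
    """Per-pixel Euclidean distance (px) to the nearest polyline segment."""
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    px = np.stack([xx.ravel(), yy.ravel()], axis=1).astype(float)
    dmin = np.full(px.shape[0], np.inf)
    for path in paths_px:
        for a, b in zip(path[:-1], path[1:]):
            ab = b - a
            denom = float(ab @ ab)
            if denom == 0:
                proj = np.zeros(px.shape[0])
            else:
                proj = np.clip((px - a) @ ab / denom, 0.0, 1.0)
            nearest = a + proj[:, None] * ab
            d = np.linalg.norm(px - nearest, axis=1)
            np.minimum(dmin, d, out=dmin)
    return dmin.reshape(h, w)


def render_structural_image(
    schedule: ReleaseSchedule,
    cfg: SimulationConfig,
    ridge_amplitude: float = 100.0,
    punctum_amplitude: float = 3000.0,
    ridge_sigma_px: float = 0.8,
    punctum_sigma_px: float = 1.0,
    mask_halfwidth_px: float = 2.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic structural-channel (TH-GFP-like) image and process mask.

    Processes are rendered as Gaussian ridges along the schedule's
    polylines; every site becomes a bright punctum whose peak is several
    times the mean process intensity, mimicking varicose swellings.
    """
    h, w = cfg.grid_shape
    px = cfg.pixel_size_um
    if schedule.process_paths_um:
        paths_px = [np.asarray(p, dtype=float) / px for p in schedule.process_paths_um]
        d = _distance_to_polylines_px((h, w), paths_px)
        image = ridge_amplitude * np.exp(-(d**2) / (2.0 * ridge_sigma_px**2))
        mask = d <= mask_halfwidth_px
    else:
        image = np.zeros((h, w))
        mask = np.zeros((h, w), dtype=bool)
    yy, xx = np.mgrid[0:h, 0:w]
    for x_um, y_um, _ in schedule.sites:
        r2 = (xx - x_um / px) ** 2 + (yy - y_um / px) ** 2
        image = image + punctum_amplitude * np.exp(-r2 / (2.0 * punctum_sigma_px**2))
        mask |= r2 <= (2.0 * punctum_sigma_px) ** 2
    return image, mask


# --------------------------------------------------------------------------
# planted spatial spread calibration
# --------------------------------------------------------------------------


def planted_hotspot_fwhm_um(
    sigma_release_um: float,
    D_um2_s: float = 110.0,
    k_uptake_s: float = 2.0,
    Kd_nM: float = 268.0,
    k_off_s: float = 0.26,
    Q_quantum: float = 1.5e4,
    pixel_size_um: float = 0.34,
) -> float:
    """Spatial FWHM (um) of the noiseless single-quantum bound-fraction map.

    Simulates one isolated quantum on a dedicated grid, takes the frame
    where the site-pixel response peaks, and applies the same
    local-background Gaussian fit the hotspot stage uses, so this is by
    construction the quantity a preset "plants" as spatial spread.
    """
    # grid wide enough for ~4x the target spreads considered here
    half = 40
    cfg = SimulationConfig(
        grid_shape=(2 * half + 1, 2 * half + 1),
        pixel_size_um=pixel_size_um,
        frame_rate_hz=20.0,
        duration_s=max(1.0, 6.0 / max(k_uptake_s, 1e-6)) + 1.0,
        D_um2_s=D_um2_s,
        k_uptake_s=k_uptake_s,
        sigma_release_um=sigma_release_um,
        Kd_nM=Kd_nM,
        k_off_s=k_off_s,
        Q_quantum=Q_quantum,
        quantal_cv=0.0,
        shot_noise=False,
        read_noise_sd=0.0,
        n_substeps=8,
    )
    x0 = y0 = half * pixel_size_um
    ev = Event(0, 0.05, 1, Q_quantum, x0, y0)
    s = _integrate_sensor_streaming([ev], cfg)
    peak = s[int(np.argmax(s[:, half, half]))]
    fit = fit_blob_fwhm(peak, (half, half))
    return fit.fwhm_px * pixel_size_um


@lru_cache(maxsize=16)
def calibrate_release_width_for_fwhm(
    target_fwhm_um: float,
    D_um2_s: float = 110.0,
    k_uptake_s: float = 2.0,
    Kd_nM: float = 268.0,
    k_off_s: float = 0.26,
    Q_quantum: float = 1.5e4,
    pixel_size_um: float = 0.34,
) -> float:
    """Release-cloud width sigma_release (um) that plants a given FWHM.

    The measured footprint grows monotonically with the initial cloud
    extent, so a bracketed bisection on the noiseless forward model
    suffices.
    """
    from scipy.optimize import brentq

    def f(log_s):
        return (
            planted_hotspot_fwhm_um(
                math.exp(log_s), D_um2_s, k_uptake_s, Kd_nM, k_off_s,
                Q_quantum, pixel_size_um,
            )
            - target_fwhm_um
        )

    lo, hi = math.log(0.1), math.log(5.0)
    return math.exp(brentq(f, lo, hi, xtol=1e-3))


# --------------------------------------------------------------------------
# scenario presets
# --------------------------------------------------------------------------

PRESET_NAMES = (
    "evoked_axon",
    "dendrite",
    "ttx",
    "spontaneous",
    "ca_free",
    "nom",
    "diffusion_fixture",
)

# The dendritic spatial spread (3.2 um FWHM) is planted by calibrating the
# release-cloud width against the noiseless single-quantum forward model;
# all presets share that width (it is a property of fusion + film capture,
# not of the compartment). The wider evoked axonal footprint emerges from
# multi-pulse release and is not separately planted.
_DENDRITE_FWHM_UM = 3.2
# strong local clearance (confinement length ~sqrt(D/k) ~ 2 um) keeps each
# hotspot compact, as DAT-rich release sites do
_PRESET_K_UPTAKE_S = 25.0


def _preset_sigma_release_um() -> float:
    return calibrate_release_width_for_fwhm(_DENDRITE_FWHM_UM, 110.0, _PRESET_K_UPTAKE_S)


def _axon_geometry(
    cfg: SimulationConfig, n_varicosities: int, n_release: int
) -> tuple[list[tuple[float, float, bool]], list[list[tuple[float, float]]]]:
    """Varicosities on three jittered axonal branches; competent subset
    chosen by greedy farthest-point so release sites stay well separated."""
    h, w = cfg.grid_shape
    px = cfg.pixel_size_um
    rng = np.random.default_rng(derive_seed(12345, "axon-geometry"))
    branch_rows = [int(h * f) for f in (0.18, 0.5, 0.82)]
    per_branch = [n_varicosities // 3 + (1 if i < n_varicosities % 3 else 0) for i in range(3)]
    positions: list[tuple[float, float]] = []
    paths: list[list[tuple[float, float]]] = []
    for row, n_b in zip(branch_rows, per_branch):
        cols = np.linspace(10, w - 11, n_b) + rng.uniform(-2, 2, size=n_b)
        rows = row + rng.uniform(-1.5, 1.5, size=n_b)
        pts = [
            snap_to_pixel_centers((c * px, r * px), px)
            for c, r in zip(np.sort(cols), rows)
        ]
        positions.extend(pts)
        paths.append([(p[0], p[1]) for p in pts])

    # greedy farthest-point selection of release-competent varicosities
    pos = np.asarray(positions)
    chosen = [int(np.argmin(np.linalg.norm(pos - pos.mean(axis=0), axis=1)))]
    while len(chosen) < n_release:
        dists = np.min(
            np.linalg.norm(pos[:, None, :] - pos[chosen][None, :, :], axis=2), axis=1
        )
        dists[chosen] = -1
        chosen.append(int(np.argmax(dists)))
    competent = set(chosen)
    sites = [(x, y, i in competent) for i, (x, y) in enumerate(positions)]
    return sites, paths



def _make_cfg(overrides: dict, **defaults) -> SimulationConfig:
    defaults.update(overrides)
    return SimulationConfig(**defaults)

def get_preset(name: str, seed: int = 0, **overrides) -> tuple[SimulationConfig, ReleaseSchedule]:
    """Named scenario presets mirroring the experimental conditions.

    - ``evoked_axon``: optically evoked 5-pulse 25 Hz trains plus sparse
      spontaneous events on an axonal arbor; 32% of varicosities are
      release competent.
    - ``dendrite``: spontaneous quantal release from sites planted every
      7.5 um along a 75 um dendritic path; hotspot spread planted at 3.2 um.
    - ``ttx``: spontaneous (mini) events only, 0.29 s^-1 per site.
    - ``spontaneous``: pre-drug spontaneous activity, 0.16 s^-1 per site.
    - ``ca_free``: no release at all.
    - ``nom``: evoked_axon with 4x slower clearance (reuptake blockade).
    - ``diffusion_fixture``: single noiseless point source with no uptake
      and a fast-equilibrating sensor, for diffusivity recovery.

    Keyword overrides replace fields of the returned SimulationConfig
    (e.g. ``duration_s=100``) or the preset knobs ``n_varicosities``,
    ``n_release``, ``n_sites``.
    """
    n_varicosities = overrides.pop("n_varicosities", 25)
    n_release = overrides.pop("n_release", 8)
    n_sites = overrides.pop("n_sites", 20)

    if name in ("evoked_axon", "ca_free", "nom"):
        k_up = _PRESET_K_UPTAKE_S
        if name == "nom":
            k_up *= 0.25
        cfg = _make_cfg(
            overrides, grid_shape=(96, 160), duration_s=30.0, k_uptake_s=k_up,
            sigma_release_um=_preset_sigma_release_um(), seed=seed,
        )
        sites, paths = _axon_geometry(cfg, n_varicosities, n_release)
        if name == "ca_free":
            schedule = ReleaseSchedule(sites=sites, evoked=[], spont_rate_hz=0.0,
                                       process_paths_um=paths)
        else:
            schedule = ReleaseSchedule(
                sites=sites,
                evoked=[StimTrain(5.0), StimTrain(17.0)],
                spont_rate_hz=0.15,
                quanta=QuantaSampler(kind="categorical"),
                process_paths_um=paths,
            )
        return cfg, schedule

    if name == "dendrite":
        cfg = _make_cfg(
            overrides, grid_shape=(48, 250), duration_s=60.0,
            k_uptake_s=_PRESET_K_UPTAKE_S,
            sigma_release_um=_preset_sigma_release_um(), seed=seed,
        )
        px = cfg.pixel_size_um
        y_path = 24 * px
        path = [(1.5, y_path), (83.0, y_path)]
        sites = []
        for j in range(30):  # puncta every 2.5 um; every third releases
            x, y = snap_to_pixel_centers((2.0 + 2.5 * j, y_path), px)
            sites.append((x, y, j % 3 == 0))
        schedule = ReleaseSchedule(
            sites=sites,
            evoked=[],
            spont_rate_hz=0.2,
            quanta=QuantaSampler(kind="categorical"),
            process_paths_um=[path],
        )
        return cfg, schedule

    if name in ("ttx", "spontaneous"):
        rate = 0.29 if name == "ttx" else 0.16
        cfg = _make_cfg(
            overrides, grid_shape=(96, 160), duration_s=60.0,
            k_uptake_s=_PRESET_K_UPTAKE_S,
            sigma_release_um=_preset_sigma_release_um(), seed=seed,
        )
        sites, paths = _axon_geometry(cfg, n_sites, n_sites)
        schedule = ReleaseSchedule(
            sites=sites,
            evoked=[],
            spont_rate_hz=rate,
            quanta=QuantaSampler(kind="categorical"),
            process_paths_um=paths,
        )
        return cfg, schedule

    if name == "diffusion_fixture":
        cfg = _make_cfg(
            overrides,
            grid_shape=(151, 151),
            frame_rate_hz=20.0,
            duration_s=1.5,
            k_uptake_s=0.0,
            k_off_s=50.0,
            Q_quantum=2.0e3,
            quantal_cv=0.0,
            shot_noise=False,
            read_noise_sd=0.0,
            n_substeps=6,
            seed=seed,
        )
        px = cfg.pixel_size_um
        x0 = y0 = 75 * px
        sites = [(x0, y0, True)]
        schedule = ReleaseSchedule(sites=sites, evoked=[], spont_rate_hz=0.0)
        # single deterministic event; encode as a one-pulse "train"
        schedule.evoked = [StimTrain(0.25, n_pulses=1, pulse_rate_hz=1.0, p_release=1.0)]
        return cfg, schedule

    raise ConfigError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")
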