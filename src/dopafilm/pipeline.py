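"""Stage orchestration: simulate -> dff -> hotspots -> kinetics -> quantal
-> diffusion -> summarize, with a JSON manifest, checksum caching and
deterministic seeding (every stochastic stage draws from a seed derived
from the run seed and the stage name)."""

from __future__ import annotations

import hashlib
import json
import time
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats as sstats

from . import __version__
from . import io as dio
from ._utils import derive_seed
from .baseline import BaselineParams, BaselineResult, compute_dff
from .biophys import estimate_variance_series, fit_diffusivity
from .errors import ConfigError, DataError, FitError
from .hotspots import (
    NnmfParams,
    centroid,
    component_trace,
    deduplicate_hotspots,
    detect_varicosities,
    filter_hotspots_by_snr,
    hotspot_spacing,
    match_hotspots,
    nnmf_decompose,
    peak_frame_image,
    spatial_fwhm,
)
from .kinetics import analyze_trace, tau_quantile_range
from .quantal import select_model, qq_table
from .simcore import GroundTruth, get_preset, generate_dataset, render_structural_image

STAGES = ("simulate", "dff", "hotspots", "kinetics", "quantal", "diffusion", "summarize")


def detect_hotspots_in_movie(
    movie,
    baseline_params: BaselineParams | None = None,
    nnmf_params: NnmfParams | None = None,
    min_snr: float = 5.0,
):
    """Movie -> (BaselineResult, hotspots with traces/centroids/FWHMs).

    The in-memory core of the dff+hotspots stages: baseline, penalized
    NNMF, SNR and compactness filtering, per-hotspot statistics on the
    averaged post-peak dF image, and duplicate/spillover removal.
    """
    base = compute_dff(movie, baseline_params)
    df_stack = base.dFF * base.F0
    hs = nnmf_decompose(
        df_stack, nnmf_params or NnmfParams(), pixel_size_um=movie.pixel_size_um
    )
    for h in hs:
        component_trace(h, base)
    hs = filter_hotspots_by_snr(hs, base, min_snr=min_snr)
    for h in hs:
        peak = peak_frame_image(df_stack, h)
        centroid(h, peak)
        spatial_fwhm(peak, h)
    return base, deduplicate_hotspots(hs)


def load_config(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    cfg = yaml.safe_load(path.read_text())
    if not isinstance(cfg, dict):
        raise ConfigError("run config must be a mapping")
    return cfg


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _stage_hash(name: str, config: dict) -> str:
    payload = json.dumps(
        {"stage": name, "seed": config.get("seed", 0),
         "preset": config.get("preset"), "params": config.get(name, {}),
         "simulate": config.get("simulate", {})},
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()


class Run:
    """One pipeline run rooted at ``outdir``; stages share state lazily."""

    def __init__(self, config: dict):
        self.config = config
        self.outdir = Path(config.get("outdir", "dopafilm_run"))
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.seed = int(config.get("seed", 0))
        self.warnings: list[str] = []
        self.manifest_path = self.outdir / "manifest.json"
        self.manifest = (
            json.loads(self.manifest_path.read_text())
            if self.manifest_path.exists()
            else {"stages": {}}
        )
        self._movie = None
        self._truth: GroundTruth | None = None
        self._baseline: BaselineResult | None = None
        self._hotspots = None

    # -- state loaders -----------------------------------------------------

    @property
    def movie(self):
        if self._movie is None:
            path = self.outdir / "movie.tif"
            if not path.exists():
                raise DataError(f"missing input {path}; run the simulate stage first")
            self._movie = dio.read_movie_tiff(path)
        return self._movie

    @property
    def truth(self) -> GroundTruth:
        if self._truth is None:
            self._truth = GroundTruth.load(self.outdir / "ground_truth.json")
        return self._truth

    @property
    def baseline(self) -> BaselineResult:
        if self._baseline is None:
            f0 = dio.read_stack_tiff(self.outdir / "f0.tif").astype(float)
            dff = dio.read_stack_tiff(self.outdir / "dff.tif").astype(float)
            self._baseline = BaselineResult(
                F0=f0, dFF=dff, params_echo=BaselineParams(**self.config.get("baseline", {}))
            )
        return self._baseline

    # -- stages ------------------------------------------------------------

    def stage_simulate(self) -> list[Path]:
        preset = self.config.get("preset", "evoked_axon")
        overrides = dict(self.config.get("simulate", {}))
        cfg, schedule = get_preset(preset, seed=derive_seed(self.seed, "simulate"), **overrides)
        movie, truth = generate_dataset(cfg, schedule, outdir=self.outdir)
        self._movie, self._truth = movie, truth
        structural, mask = render_structural_image(schedule, cfg)
        dio.write_stack_tiff(structural[None], self.outdir / "structural.tif")
        dio.write_stack_tiff(mask[None].astype(np.float32), self.outdir / "process_mask.tif")
        return [self.outdir / p for p in
                ("movie.tif", "ground_truth.json", "structural.tif", "process_mask.tif")]

    def stage_dff(self) -> list[Path]:
        params = BaselineParams(**self.config.get("baseline", {}))
        result = compute_dff(self.movie, params)
        if not result.converged:
            self.warnings.append("baseline smoothing hit the iteration cap")
        self._baseline = result
        dio.write_stack_tiff(result.F0, self.outdir / "f0.tif")
        dio.write_stack_tiff(result.dFF, self.outdir / "dff.tif")
        return [self.outdir / "f0.tif", self.outdir / "dff.tif"]

    def _compute_hotspots(self):
        if self._hotspots is not None:
            return self._hotspots
        params = NnmfParams(
            seed=derive_seed(self.seed, "nnmf"), **self.config.get("nnmf", {})
        )
        base = self.baseline
        df_stack = base.dFF * base.F0
        hs = nnmf_decompose(df_stack, params, pixel_size_um=self.movie.pixel_size_um)
        for h in hs:
            component_trace(h, base)
        min_snr = float(self.config.get("detection", {}).get("min_snr", 5.0))
        hs = filter_hotspots_by_snr(hs, base, min_snr=min_snr)
        for h in hs:
            peak = peak_frame_image(df_stack, h)
            centroid(h, peak)
            spatial_fwhm(peak, h)
        self._hotspots = deduplicate_hotspots(hs)
        return self._hotspots

    def stage_hotspots(self) -> list[Path]:
        hs = self._compute_hotspots()
        px = self.movie.pixel_size_um
        structural = dio.read_stack_tiff(self.outdir / "structural.tif")[0]
        mask = dio.read_stack_tiff(self.outdir / "process_mask.tif")[0] > 0.5
        match_cfg = self.config.get("match", {})
        varic = detect_varicosities(structural, mask, px)
        hs_centroids = [h.centroid_um for h in hs]
        match = match_hotspots(
            hs_centroids, varic.centroids_um,
            max_radius_um=float(match_cfg.get("max_radius_um", 1.7)),
        )
        matched_by_hotspot = {m["hotspot"]: m for m in match["matches"]}
        rows = []
        for i, h in enumerate(hs):
            m = matched_by_hotspot.get(i)
            rows.append(
                {
                    "component_index": h.component_index,
                    "centroid_x_um": h.centroid_um[0],
                    "centroid_y_um": h.centroid_um[1],
                    "spatial_fwhm_um": h.spatial_fwhm_um,
                    "matched_varicosity": m["varicosity"] if m else -1,
                    "offset_um": m["offset_um"] if m else np.nan,
                }
            )
        table = pd.DataFrame(rows)
        table.to_csv(self.outdir / "hotspot_table.csv", index=False)

        times = self.movie.times()
        traces = pd.DataFrame({"frame": np.arange(len(times)), "time_s": times})
        for h in hs:
            traces[f"dff_{h.component_index}"] = h.trace_dff
        traces.to_csv(self.outdir / "traces.csv", index=False)
        if hs:
            dio.write_stack_tiff(
                np.stack([h.spatial_map for h in hs]), self.outdir / "maps.tif"
            )

        summary = {
            "n_hotspots": len(hs),
            "n_varicosities": len(varic.centroids_um),
            "competent_fraction": match["competent_fraction"],
            "n_matched": len(match["matches"]),
        }
        path = self.truth.dendrite_path_um
        if path is not None and len(hs_centroids) >= 2:
            spacing = hotspot_spacing(hs_centroids, path)
            summary["spacing_mean_um"] = spacing["mean_um"]
            summary["spacing_sd_um"] = spacing["sd_um"]
        (self.outdir / "hotspot_summary.json").write_text(json.dumps(summary, indent=1))
        outputs = ["hotspot_table.csv", "traces.csv", "hotspot_summary.json"]
        if hs:
            outputs.append("maps.tif")
        return [self.outdir / p for p in outputs]

    def stage_kinetics(self) -> list[Path]:
        traces = pd.read_csv(self.outdir / "traces.csv")
        fr = self.movie.frame_rate_hz
        kcfg = self.config.get("kinetics", {})
        rows = []
        taus = []
        for col in [c for c in traces.columns if c.startswith("dff_")]:
            comp = int(col.split("_")[1])
            summary = analyze_trace(
                traces[col].to_numpy(), fr,
                min_prominence=float(kcfg.get("min_prominence", 0.02)),
                min_snr=float(kcfg.get("min_snr", 5.0)),
            )
            for ev in summary.events:
                rows.append(
                    {
                        "component_index": comp,
                        "t_peak_s": ev.t_peak_s,
                        "amplitude_pct": ev.amplitude_pct,
                        "fwhm_s": ev.fwhm_s,
                        "tau_off_s": ev.tau_off_s,
                        "tau_peak_s": ev.tau_peak_s,
                        "snr": ev.snr,
                        "event_rate_hz": summary.event_rate_hz,
                    }
                )
                if ev.tau_off_s is not None:
                    taus.append(ev.tau_off_s)
        events = pd.DataFrame(
            rows,
            columns=["component_index", "t_peak_s", "amplitude_pct", "fwhm_s",
                     "tau_off_s", "tau_peak_s", "snr", "event_rate_hz"],
        )
        events.to_csv(self.outdir / "events.csv", index=False)
        pop = {
            "n_events": len(events),
            "tau_10_90_s": tau_quantile_range(taus),
            "mean_rate_hz": float(events["event_rate_hz"].mean()) if len(events) else 0.0,
        }
        (self.outdir / "kinetics_summary.json").write_text(json.dumps(pop, indent=1))
        return [self.outdir / "events.csv", self.outdir / "kinetics_summary.json"]

    def stage_quantal(self) -> list[Path]:
        events = pd.read_csv(self.outdir / "events.csv")
        amps = events["amplitude_pct"].dropna().to_numpy()
        outputs = [self.outdir / "quantal_aic.csv"]
        if len(amps) < 20:
            self.warnings.append(
                f"quantal stage skipped: {len(amps)} amplitude samples (<20)"
            )
            pd.DataFrame(columns=["model", "n_params", "loglik", "aic", "selected"]).to_csv(
                outputs[0], index=False
            )
            return outputs
        qcfg = self.config.get("quantal", {})
        fit = select_model(
            amps, k_max=int(qcfg.get("k_max", 4)),
            n_restarts=int(qcfg.get("n_restarts", 10)),
            seed=derive_seed(self.seed, "quantal"),
        )
        pd.DataFrame(fit.aic_table).to_csv(outputs[0], index=False)
        params = {
            "selected": fit.selected,
            "gmm": [
                {"k": m.k, "means": m.means.tolist(), "sds": m.sds.tolist(),
                 "weights": m.weights.tolist(), "aic": m.aic}
                for m in fit.candidates
            ],
            "lognormal": (
                {"mu": fit.lognormal.mu, "sigma": fit.lognormal.sigma,
                 "aic": None if fit.lognormal.degenerate else fit.lognormal.aic}
                if fit.lognormal else None
            ),
        }
        (self.outdir / "quantal_params.json").write_text(json.dumps(params, indent=1))
        qq = qq_table(amps, fit.selected_model)
        pd.DataFrame(qq, columns=["theoretical_q", "empirical_q"]).to_csv(
            self.outdir / "qq.csv", index=False
        )
        outputs += [self.outdir / "quantal_params.json", self.outdir / "qq.csv"]
        return outputs

    def stage_diffusion(self) -> list[Path]:
        base = self.baseline
        hs = self._compute_hotspots()
        events = pd.read_csv(self.outdir / "events.csv")
        fr = self.movie.frame_rate_hz
        px = self.movie.pixel_size_um
        df_stack = base.dFF * base.F0
        rows = []
        if len(events):
            best = events.sort_values("snr", ascending=False).head(
                int(self.config.get("diffusion", {}).get("n_events", 3))
            )
            for _, ev in best.iterrows():
                comp = int(ev["component_index"])
                hsp = next((h for h in hs if h.component_index == comp), None)
                if hsp is None or hsp.centroid_um is None:
                    continue
                pk = int(round(ev["t_peak_s"] * fr))
                frames = df_stack[pk : pk + 8]
                times = np.arange(frames.shape[0]) / fr
                try:
                    tt, s2 = estimate_variance_series(
                        frames, (hsp.centroid_um[0] / px, hsp.centroid_um[1] / px),
                        times, px,
                    )
                    est = fit_diffusivity(tt, s2)
                except (FitError, DataError):
                    continue
                rows.append(
                    {"component_index": comp, "t_peak_s": ev["t_peak_s"],
                     "D_um2_s": est.D_um2_s, "D_cm2_s": est.D_cm2_s,
                     "r2": est.r2, "n_frames": len(tt)}
                )
        pd.DataFrame(
            rows, columns=["component_index", "t_peak_s", "D_um2_s", "D_cm2_s", "r2", "n_frames"]
        ).to_csv(self.outdir / "diffusion.csv", index=False)
        if not rows:
            self.warnings.append("diffusion stage: no event produced a usable variance series")
        return [self.outdir / "diffusion.csv"]

    def stage_summarize(self) -> list[Path]:
        tables = summarize(self.outdir)
        out = self.outdir / "summary_stats.csv"
        tables.to_csv(out, index=False)
        return [out]

    # -- driver ------------------------------------------------------------

    def execute(self, stages: list[str] | None = None) -> dict:
        stages = list(stages or self.config.get("stages", STAGES))
        for s in stages:
            if s not in STAGES:
                raise ConfigError(f"unknown stage {s!r}")
        for name in STAGES:
            if name not in stages:
                continue
            shash = _stage_hash(name, self.config)
            cached = self.manifest["stages"].get(name)
            if cached and cached.get("hash") == shash and all(
                Path(p).exists() for p in cached["outputs"]
            ):
                continue  # checksummed cache hit: touch nothing
            t0 = time.perf_counter()
            outputs = getattr(self, f"stage_{name}")()
            self.manifest["stages"][name] = {
                "hash": shash,
                "outputs": [str(p) for p in outputs],
                "checksums": {p.name: _sha256(p) for p in outputs},
                "elapsed_s": round(time.perf_counter() - t0, 3),
            }
        self.manifest["config"] = self.config
        self.manifest["version"] = __version__
        self.manifest["warnings"] = self.warnings
        self.manifest_path.write_text(json.dumps(self.manifest, indent=1))
        return self.manifest


def run(config: dict | str | Path, stages: list[str] | None = None) -> dict:
    """Execute a pipeline run from a config mapping or YAML path."""
    if not isinstance(config, dict):
        config = load_config(config)
    return Run(config).execute(stages)


# --------------------------------------------------------------------------
# summaries
# --------------------------------------------------------------------------

_SUMMARY_METRICS = ("amplitude_pct", "fwhm_s", "tau_off_s", "tau_peak_s", "snr")


def _describe(values: np.ndarray, metric: str, condition: str) -> dict:
    q25, q50, q75 = np.percentile(values, [25, 50, 75])
    return {
        "condition": condition, "metric": metric, "n": len(values),
        "median": q50, "q25": q25, "q75": q75,
        "mean": values.mean(), "sd": values.std(ddof=1) if len(values) > 1 else 0.0,
    }


def summarize(results_dir: str | Path, condition: str | None = None) -> pd.DataFrame:
    """Median/quartile/mean+-SD tables for the kinetic and spatial metrics."""
    results_dir = Path(results_dir)
    condition = condition or results_dir.name
    rows = []
    events_path = results_dir / "events.csv"
    if events_path.exists():
        events = pd.read_csv(events_path)
        for metric in _SUMMARY_METRICS:
            vals = events[metric].dropna().to_numpy() if metric in events else np.array([])
            if len(vals):
                rows.append(_describe(vals, metric, condition))
    table_path = results_dir / "hotspot_table.csv"
    if table_path.exists():
        table = pd.read_csv(table_path)
        vals = table["spatial_fwhm_um"].dropna().to_numpy()
        if len(vals):
            rows.append(_describe(vals, "spatial_fwhm_um", condition))
    return pd.DataFrame(
        rows, columns=["condition", "metric", "n", "median", "q25", "q75", "mean", "sd"]
    )


def compare_conditions(
    dir_a: str | Path, dir_b: str | Path, metrics=_SUMMARY_METRICS
) -> pd.DataFrame:
    """Unpaired two-tailed t-tests between two runs, metric by metric."""
    rows = []
    for metric in metrics:
        vals = []
        for d in (dir_a, dir_b):
            events = pd.read_csv(Path(d) / "events.csv")
            vals.append(events[metric].dropna().to_numpy() if metric in events else np.array([]))
        a, b = vals
        if len(a) < 2 or len(b) < 2:
            continue
        t, p = sstats.ttest_ind(a, b)
        rows.append(
            {"metric": metric, "mean_a": a.mean(), "mean_b": b.mean(),
             "t": float(t), "p": float(p), "n_a": len(a), "n_b": len(b)}
        )
    return pd.DataFrame(rows, columns=["metric", "mean_a", "mean_b", "t", "p", "n_a", "n_b"])


def two_sample_t(a, b) -> tuple[float, float]:
    """Student's unpaired two-tailed t statistic and p-value."""
    t, p = sstats.ttest_ind(np.asarray(a, float), np.asarray(b, float))
    return float(t), float(p)
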