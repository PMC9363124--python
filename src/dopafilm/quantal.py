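"""Quantal amplitude analysis: Gaussian mixtures vs a lognormal, scored by AIC.

Peak-amplitude samples (% dFF) are fitted with 1..k_max-component Gaussian
mixtures by EM and with a single lognormal; the model with the lowest
AIC = 2p - 2 logL wins. A k-component 1D mixture has 3k - 1 free parameters
(k means, k SDs, k-1 independent weights); the lognormal has 2. A
quantile-quantile table against the selected model supports graphical
discrimination.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq
from scipy.special import logsumexp
from scipy.stats import norm

from ._utils import derive_seed
from .errors import DataError, FitError

__all__ = [
    "MixtureModel",
    "LognormalModel",
    "QuantalFit",
    "fit_gmm",
    "aic",
    "fit_lognormal",
    "select_model",
    "qq_table",
    "mixture_cdf",
    "mixture_ppf",
]


def aic(loglik: float, n_params: int) -> float:
    """Akaike information criterion: 2*parameters - 2*log-likelihood."""
    if not np.isfinite(loglik):
        raise DataError("log-likelihood must be finite")
    return 2.0 * n_params - 2.0 * loglik


@dataclass
class MixtureModel:
    k: int
    means: np.ndarray  # ascending
    sds: np.ndarray
    weights: np.ndarray  # simplex
    loglik: float
    loglik_path: list[float] = field(default_factory=list)
    converged: bool = True

    @property
    def n_params(self) -> int:
        return 3 * self.k - 1

    @property
    def aic(self) -> float:
        return aic(self.loglik, self.n_params)

    def logpdf(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        comp = norm.logpdf(x, self.means, self.sds) + np.log(self.weights)
        return logsumexp(comp, axis=-1)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)[..., None]
        return np.sum(self.weights * norm.cdf(x, self.means, self.sds), axis=-1)


@dataclass
class LognormalModel:
    mu: float
    sigma: float
    loglik: float
    degenerate: bool = False
    n_params: int = 2

    @property
    def aic(self) -> float:
        return aic(self.loglik, self.n_params)

    def cdf(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        out = np.zeros_like(x, dtype=float)
        pos = x > 0
        out[pos] = norm.cdf((np.log(x[pos]) - self.mu) / self.sigma)
        return out

    def ppf(self, p) -> np.ndarray:
        return np.exp(self.mu + self.sigma * norm.ppf(p))


@dataclass
class QuantalFit:
    candidates: list[MixtureModel]
    lognormal: LognormalModel | None
    selected: str  # "gmm_k" or "lognormal"
    aic_table: list[dict]
    qq: list[tuple[float, float]] | None = None

    @property
    def selected_model(self):
        if self.selected == "lognormal":
            return self.lognormal
        k = int(self.selected.split("_")[1])
        return next(m for m in self.candidates if m.k == k)


def _em_once(
    x: np.ndarray, k: int, rng: np.random.Generator | None,
    max_iter: int, tol: float, sd_floor: float,
) -> MixtureModel:
    n = len(x)
    # quantile-spread means; restarts jitter them
    qs = (np.arange(k) + 0.5) / k
    means = np.quantile(x, qs)
    if rng is not None:
        means = means + rng.normal(0.0, x.std() / (2 * k), size=k)
    sds = np.full(k, max(x.std(), sd_floor))
    weights = np.full(k, 1.0 / k)

    path = []
    converged = False
    for _ in range(max_iter):
        log_comp = (
            norm.logpdf(x[:, None], means[None, :], sds[None, :])
            + np.log(weights)[None, :]
        )
        log_norm = logsumexp(log_comp, axis=1)
        path.append(float(log_norm.sum()))
        resp = np.exp(log_comp - log_norm[:, None])
        nk = resp.sum(axis=0) + 1e-300
        weights = nk / n
        means = (resp * x[:, None]).sum(axis=0) / nk
        var = (resp * (x[:, None] - means[None, :]) ** 2).sum(axis=0) / nk
        sds = np.sqrt(np.maximum(var, sd_floor**2))
        if len(path) > 1 and abs(path[-1] - path[-2]) < tol * (1 + abs(path[-1])):
            converged = True
            break
    # final log-likelihood with the last parameter set
    log_comp = (
        norm.logpdf(x[:, None], means[None, :], sds[None, :]) + np.log(weights)[None, :]
    )
    loglik = float(logsumexp(log_comp, axis=1).sum())
    path.append(loglik)
    order = np.argsort(means)
    return MixtureModel(
        k=k, means=means[order], sds=sds[order], weights=weights[order],
        loglik=loglik, loglik_path=path, converged=converged,
    )


def fit_gmm(
    samples,
    k: int,
    n_restarts: int = 10,
    seed: int = 0,
    max_iter: int = 500,
    tol: float = 1e-8,
) -> MixtureModel:
    """EM fit of a k-component 1D Gaussian mixture; best of n_restarts.

    SDs are floored at 1e-3 of the sample SD to prevent likelihood
    collapse onto single points.
    """
    x = np.asarray(samples, dtype=float)
    if x.ndim != 1 or not np.isfinite(x).all():
        raise DataError("samples must be a finite 1D array")
    if len(x) < 5 * k:
        raise DataError(f"need >= {5 * k} samples for k={k}")
    if np.ptp(x) == 0:
        raise FitError("degenerate sample: all values identical")
    sd_floor = 1e-3 * x.std()
    best = _em_once(x, k, None, max_iter, tol, sd_floor)
    for r in range(1, n_restarts):
        rng = np.random.default_rng(derive_seed(seed, f"gmm-k{k}-r{r}"))
        cand = _em_once(x, k, rng, max_iter, tol, sd_floor)
        if cand.loglik > best.loglik:
            best = cand
    return best


def fit_lognormal(samples) -> LognormalModel:
    """Exact MLE of a lognormal: mu, sigma are the mean/SD of log samples."""
    x = np.asarray(samples, dtype=float)
    if np.any(x <= 0):
        raise DataError("lognormal requires strictly positive samples")
    logs = np.log(x)
    mu = float(logs.mean())
    sigma = float(logs.std())  # MLE uses 1/n
    # floating-point spread of identical samples is still degenerate
    degenerate = sigma <= 1e-12 * max(abs(mu), 1.0)
    if degenerate:
        sigma = 0.0
    if degenerate:
        loglik = np.inf  # point mass; flagged, not comparable
    else:
        loglik = float(
            np.sum(-np.log(x * sigma * np.sqrt(2 * np.pi)) - (logs - mu) ** 2 / (2 * sigma**2))
        )
    return LognormalModel(mu=mu, sigma=sigma, loglik=loglik, degenerate=degenerate)


def select_model(
    samples, k_max: int = 4, n_restarts: int = 10, seed: int = 0
) -> QuantalFit:
    """Fit GMMs k=1..k_max plus a lognormal; select the minimum AIC.

    Ties break toward fewer parameters. The full AIC table is retained.
    """
    x = np.asarray(samples, dtype=float)
    if len(x) < 20:
        raise DataError("need >= 20 samples for model selection")
    candidates = [fit_gmm(x, k, n_restarts=n_restarts, seed=seed) for k in range(1, k_max + 1)]
    logn = fit_lognormal(x) if np.all(x > 0) else None
    entries = [
        {"model": f"gmm_{m.k}", "n_params": m.n_params, "loglik": m.loglik, "aic": m.aic}
        for m in candidates
    ]
    if logn is not None and not logn.degenerate:
        entries.append(
            {"model": "lognormal", "n_params": logn.n_params, "loglik": logn.loglik,
             "aic": logn.aic}
        )
    # min AIC; ties toward fewer parameters
    best = min(entries, key=lambda e: (e["aic"], e["n_params"]))
    for e in entries:
        e["selected"] = e["model"] == best["model"]
    return QuantalFit(
        candidates=candidates, lognormal=logn, selected=best["model"], aic_table=entries
    )


def mixture_cdf(model: MixtureModel, x) -> np.ndarray:
    return model.cdf(x)


def mixture_ppf(model: MixtureModel, p: float, tol: float = 1e-10) -> float:
    """Numerically invert the mixture CDF by bracketed bisection."""
    lo = float(np.min(model.means - 10 * model.sds))
    hi = float(np.max(model.means + 10 * model.sds))
    # expand until bracketed (CDF is monotone)
    while model.cdf(lo) > p:
        lo -= (hi - lo)
    while model.cdf(hi) < p:
        hi += (hi - lo)
    return float(brentq(lambda v: float(model.cdf(v)) - p, lo, hi, xtol=tol))


def qq_table(samples, model) -> list[tuple[float, float]]:
    """(theoretical quantile, empirical quantile) pairs at plotting
    positions p_i = (i - 0.5)/n; the identity line indicates a good fit."""
    x = np.sort(np.asarray(samples, dtype=float))
    n = len(x)
    ps = (np.arange(1, n + 1) - 0.5) / n
    if isinstance(model, MixtureModel):
        theo = [mixture_ppf(model, p) for p in ps]
    else:
        theo = list(np.asarray(model.ppf(ps), dtype=float))
    return list(zip([float(t) for t in theo], [float(v) for v in x]))
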