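"""Amyloid positivity from SUVR via a two-component Gaussian mixture.

The SUVR distribution of a cognitively normal ~70-year-old cohort is
bimodal: a tight amyloid-negative mode and a broader amyloid-positive mode.
A 1-D two-component Gaussian mixture is fitted by EM and the positivity
threshold is the 99th percentile of the lower (amyloid-negative) component,

    cut = mu_low + Phi^{-1}(0.99) * sigma_low,

with values strictly above the cut classified positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .config import EMConfig

__all__ = [
    "SuvrMixtureModel",
    "SuvrMixtureResults",
    "fit_two_gaussian_mixture",
    "cut_point_99",
    "classify_abeta",
]

_Z99 = float(stats.norm.ppf(0.99))  # 2.3263...


class MixtureFitError(RuntimeError):
    """EM failed to converge or the data are degenerate."""


@dataclass(frozen=True)
class SuvrMixtureResults:
    """Converged two-component fit, components ordered mu1 <= mu2."""

    mu: tuple[float, float]
    sigma: tuple[float, float]
    weights: tuple[float, float]
    log_likelihood: float
    n_iterations: int
    n_obs: int
    converged: bool

    @property
    def cut_point(self) -> float:
        return cut_point_99(self.mu[0], self.sigma[0])

    def responsibilities(self, x) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        log_p = np.stack(
            [
                np.log(w) + stats.norm.logpdf(x, m, s)
                for w, m, s in zip(self.weights, self.mu, self.sigma)
            ]
        )
        log_p -= log_p.max(axis=0, keepdims=True)
        p = np.exp(log_p)
        return (p / p.sum(axis=0, keepdims=True)).T

    def classify(self, suvr) -> np.ndarray:
        return classify_abeta(suvr, self.cut_point)

    def summary(self) -> str:
        lines = [
            "Two-component Gaussian SUVR mixture",
            "=" * 42,
            f"n = {self.n_obs}, iterations = {self.n_iterations}, "
            f"log-likelihood = {self.log_likelihood:.4f}",
            f"lower : mu = {self.mu[0]:.4f}, sigma = {self.sigma[0]:.4f}, "
            f"weight = {self.weights[0]:.3f}",
            f"upper : mu = {self.mu[1]:.4f}, sigma = {self.sigma[1]:.4f}, "
            f"weight = {self.weights[1]:.3f}",
            f"cut point (99th pct of lower) = {self.cut_point:.4f}",
        ]
        return "\n".join(lines)


class SuvrMixtureModel:
    """EM for a 1-D two-component Gaussian mixture.

    Initialisation splits at the sample median (moments per half), with
    jittered split quantiles across restarts; the best restart by final
    log-likelihood wins.  Component SDs are floored to avoid degenerate
    collapse onto a single observation.
    """

    def __init__(self, suvr, config: EMConfig = EMConfig()):
        x = np.asarray(suvr, dtype=float)
        x = x[np.isfinite(x)]
        if x.size < 10:
            raise MixtureFitError(f"need >= 10 finite SUVR values, got {x.size}")
        if np.ptp(x) < 1e-12:
            raise MixtureFitError("all SUVR values identical; mixture is degenerate")
        self.x = x
        self.config = config

    def _init_params(self, q: float) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        x = np.sort(self.x)
        k = int(np.clip(round(q * len(x)), 2, len(x) - 2))
        lo, hi = x[:k], x[k:]
        floor = self.config.sigma_floor
        mu = np.array([lo.mean(), hi.mean()])
        sigma = np.array([max(lo.std(), floor), max(hi.std(), floor)])
        w = np.array([k / len(x), 1 - k / len(x)])
        return mu, sigma, w

    def _em(self, mu, sigma, w):
        x = self.x
        cfg = self.config
        prev_ll = -np.inf
        for it in range(1, cfg.max_iter + 1):
            log_p = np.stack(
                [np.log(w[k]) + stats.norm.logpdf(x, mu[k], sigma[k]) for k in range(2)]
            )
            m = log_p.max(axis=0)
            ll = float(np.sum(m + np.log(np.exp(log_p - m).sum(axis=0))))
            r = np.exp(log_p - m)
            r /= r.sum(axis=0, keepdims=True)
            nk = r.sum(axis=1)
            if np.any(nk < 1e-10):
                return mu, sigma, w, -np.inf, it, False
            mu = (r @ x) / nk
            var = np.array([(r[k] @ (x - mu[k]) ** 2) / nk[k] for k in range(2)])
            if cfg.equal_variance:
                var[:] = (nk @ var) / nk.sum()
            sigma = np.sqrt(np.clip(var, cfg.sigma_floor**2, None))
            w = nk / len(x)
            if ll - prev_ll < cfg.tol and it > 1:
                return mu, sigma, w, ll, it, True
            prev_ll = ll
        return mu, sigma, w, prev_ll, cfg.max_iter, False

    def fit(self, seed: int = 0) -> SuvrMixtureResults:
        rng = np.random.default_rng(seed)
        best = None
        diagnostics = []
        for i in range(self.config.n_restarts):
            q = 0.5 if i == 0 else float(np.clip(0.5 + 0.25 * rng.standard_normal(), 0.1, 0.9))
            mu, sigma, w, ll, it, conv = self._em(*self._init_params(q))
            diagnostics.append((q, ll, it, conv))
            if conv and (best is None or ll > best[3]):
                best = (mu, sigma, w, ll, it)
        if best is None:
            raise MixtureFitError(
                "EM failed to converge in all restarts; "
                f"diagnostics (split q, loglik, iters, converged): {diagnostics}"
            )
        mu, sigma, w, ll, it = best
        order = np.argsort(mu)
        return SuvrMixtureResults(
            mu=tuple(float(mu[k]) for k in order),
            sigma=tuple(float(sigma[k]) for k in order),
            weights=tuple(float(w[k]) for k in order),
            log_likelihood=ll,
            n_iterations=it,
            n_obs=len(self.x),
            converged=True,
        )


def fit_two_gaussian_mixture(
    suvr, config: EMConfig = EMConfig(), seed: int = 0
) -> SuvrMixtureResults:
    """Functional front-end over :class:`SuvrMixtureModel`."""
    return SuvrMixtureModel(suvr, config).fit(seed=seed)


def cut_point_99(mu_lower: float, sigma_lower: float) -> float:
    """99th percentile of the lower component: mu + 2.3263...*sigma."""
    if sigma_lower <= 0:
        raise ValueError("sigma of the lower component must be > 0")
    return float(mu_lower + _Z99 * sigma_lower)


def classify_abeta(suvr, cut: float):
    """Positive iff SUVR strictly exceeds the cut (boundary is negative)."""
    x = np.asarray(suvr, dtype=float)
    out = (x > cut).astype(int)
    if out.ndim == 0:
        return int(out)
    return out
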