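"""Univariate Gaussian mixture models fitted by expectation-maximization.

The mixture density over one collective variable is

    p(x) = sum_k phi_k N(x | mu_k, sigma_k),   sum_k phi_k = 1,

with N the normal density and sigma_k a *standard deviation*.  The default
K = 3 components reconstruct typical CV distributions well.  The fit is the
ingredient of the adaptive bias: the bias potential of replica r is
(r-1) * Delta * p(x), so the density and its derivative must be cheap and
smooth.

EM here is deterministic given a seed: initial responsibilities come from a
seeded k-means-style assignment, widths are floored at 1e-3 of the sample
range, and the per-iteration log-likelihood sequence is retained (it is
provably non-decreasing, a useful self-check).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["GMMModel", "fit_gmm", "gmm_density", "gmm_density_derivative"]

_SQRT2PI = np.sqrt(2.0 * np.pi)

#: width floor as a fraction of the sample range
VARIANCE_FLOOR_FRACTION = 1e-3


@dataclass
class GMMModel:
    """Weights, means and widths (standard deviations) of a univariate GMM."""

    weights: np.ndarray
    means: np.ndarray
    widths: np.ndarray
    n_samples: int = 0
    log_likelihood: float = np.nan
    log_likelihood_path: Optional[np.ndarray] = None
    seed: Optional[int] = None
    converged: bool = True

    def __post_init__(self):
        self.weights = np.asarray(self.weights, dtype=float)
        self.means = np.asarray(self.means, dtype=float)
        self.widths = np.asarray(self.widths, dtype=float)
        if not (self.weights.shape == self.means.shape == self.widths.shape):
            raise ValueError("weights, means, widths must have equal length K")
        if np.any(self.weights < -1e-12) or abs(self.weights.sum() - 1.0) > 1e-12:
            raise ValueError("weights must be non-negative and sum to 1")
        if np.any(self.widths <= 0):
            raise ValueError("widths must be positive")

    @property
    def K(self) -> int:
        return len(self.weights)

    def to_dict(self) -> dict:
        return {
            "K": self.K,
            "weights": self.weights.tolist(),
            "means": self.means.tolist(),
            "widths": self.widths.tolist(),
            "n_samples": int(self.n_samples),
            "log_likelihood": None if np.isnan(self.log_likelihood) else float(self.log_likelihood),
            "seed": self.seed,
            "converged": bool(self.converged),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GMMModel":
        return cls(
            weights=np.array(d["weights"]), means=np.array(d["means"]),
            widths=np.array(d["widths"]), n_samples=d.get("n_samples", 0),
            log_likelihood=(np.nan if d.get("log_likelihood") is None
                            else d["log_likelihood"]),
            seed=d.get("seed"), converged=d.get("converged", True),
        )

    def to_json(self) -> str:
        return json.dumps(self.to_dict())

    @classmethod
    def from_json(cls, s: str) -> "GMMModel":
        return cls.from_dict(json.loads(s))


def gmm_density(model: GMMModel, x) -> np.ndarray:
    """Mixture density p(x); accepts scalars or arrays."""
    x = np.asarray(x, dtype=float)
    z = (x[..., None] - model.means) / model.widths
    comp = np.exp(-0.5 * z * z) / (model.widths * _SQRT2PI)
    out = comp @ model.weights
    return out if out.ndim else float(out)


def gmm_density_derivative(model: GMMModel, x) -> np.ndarray:
    """dp/dx = sum_k phi_k N(x|mu_k,sigma_k) * (-(x-mu_k)/sigma_k^2)."""
    x = np.asarray(x, dtype=float)
    z = (x[..., None] - model.means) / model.widths
    comp = np.exp(-0.5 * z * z) / (model.widths * _SQRT2PI)
    out = (comp * (-z / model.widths)) @ model.weights
    return out if out.ndim else float(out)


def _kmeans_init(x: np.ndarray, K: int, rng: np.random.Generator, floor: float):
    """Seeded k-means (Lloyd, few sweeps) giving initial mixture parameters."""
    centers = np.sort(rng.choice(x, size=K, replace=False))
    for _ in range(10):
        assign = np.argmin(np.abs(x[:, None] - centers), axis=1)
        for k in range(K):
            sel = assign == k
            if sel.any():
                centers[k] = x[sel].mean()
    assign = np.argmin(np.abs(x[:, None] - centers), axis=1)
    w = np.empty(K)
    mu = np.empty(K)
    sig = np.empty(K)
    for k in range(K):
        sel = assign == k
        w[k] = max(sel.mean(), 1.0 / len(x))
        mu[k] = x[sel].mean() if sel.any() else centers[k]
        sig[k] = x[sel].std() if sel.sum() > 1 else floor
    w /= w.sum()
    return w, mu, np.maximum(sig, floor)


def fit_gmm(
    samples: Sequence[float],
    K: int = 3,
    seed: int = 0,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> GMMModel:
    """Fit a K-component univariate GMM by EM.

    Requires at least ``10 * K`` finite samples.  Convergence is declared when
    the relative change of the mean log-likelihood falls below ``tol``.
    Degenerate all-equal samples yield a single effective component at that
    value with a floored width.  Identical (samples, seed) give an identical
    model.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if not np.isfinite(x).all():
        raise ValueError("samples must be finite")
    if len(x) < 10 * K:
        raise ValueError(
            f"need at least {10 * K} samples to fit K={K} components, got "
            f"{len(x)}; extend the sampling interval"
        )
    rng = np.random.default_rng(seed)
    rng_span = x.max() - x.min()
    floor = VARIANCE_FLOOR_FRACTION * (rng_span if rng_span > 0
                                       else max(abs(x[0]), 1.0))

    if rng_span == 0.0:
        w = np.zeros(K)
        w[0] = 1.0
        return GMMModel(weights=w, means=np.full(K, x[0]),
                        widths=np.full(K, floor), n_samples=len(x),
                        log_likelihood=float(np.log(1.0 / (floor * _SQRT2PI))),
                        seed=seed)

    w, mu, sig = _kmeans_init(x, K, rng, floor)

    from ._kernels import em_univariate

    if em_univariate is not None:
        path, n_iter, converged = em_univariate(
            np.ascontiguousarray(x), w, mu, sig, floor, tol, max_iter)
        w = np.maximum(w, 0.0)
        w /= w.sum()
        return GMMModel(
            weights=w, means=mu, widths=sig, n_samples=len(x),
            log_likelihood=float(path[-1]), log_likelihood_path=np.array(path),
            seed=seed, converged=bool(converged),
        )

    ll_path = []
    prev = -np.inf
    converged = False
    for _ in range(max_iter):
        # E step (log-sum-exp for stability)
        z = (x[:, None] - mu) / sig
        logc = -0.5 * z * z - np.log(sig * _SQRT2PI) + np.log(w)
        m = logc.max(axis=1, keepdims=True)
        lse = m[:, 0] + np.log(np.exp(logc - m).sum(axis=1))
        ll = lse.mean()
        ll_path.append(ll)
        resp = np.exp(logc - lse[:, None])
        # M step
        nk = resp.sum(axis=0)
        w = nk / len(x)
        mu = (resp * x[:, None]).sum(axis=0) / np.maximum(nk, 1e-300)
        var = (resp * (x[:, None] - mu) ** 2).sum(axis=0) / np.maximum(nk, 1e-300)
        sig = np.maximum(np.sqrt(var), floor)
        if np.isfinite(prev) and abs(ll - prev) <= tol * max(abs(prev), 1e-12):
            converged = True
            break
        prev = ll
    w = np.maximum(w, 0.0)
    w /= w.sum()
    return GMMModel(
        weights=w, means=mu, widths=sig, n_samples=len(x),
        log_likelihood=float(ll_path[-1]), log_likelihood_path=np.array(ll_path),
        seed=seed, converged=converged,
    )
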