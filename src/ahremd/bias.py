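"""Per-replica adaptive bias potentials built from GMM density estimates.

Replica r (1-based) carries the bias

    B_r(x) = sum_CV (r - 1) * Delta * p_CV(x_CV),

where p_CV is the mixture density most recently fitted to the pooled CV
samples of *all* replicas over a sliding window of past intervals, and Delta
is the per-replica increment (default 4 thermal-energy units).  Replica 1 —
the reference replica — is always unbiased, so its samples follow the plain
Boltzmann distribution.  Because p peaks where sampling has concentrated, the
bias destabilizes the currently sampled region and pushes higher replicas
outward; exchanges then feed the newly reached configurations back down the
ladder.

Note on units: p(x) has units of 1/CV-length, so the effective bias height
depends on the CV scale.  Delta is interpreted in the system's energy units
(multiples of kT for the reduced-unit toy systems).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence

import numpy as np

from .cv import CVDefinition, compute_cv_batch, cv_gradient_batch
from .gmm import GMMModel, fit_gmm, gmm_density, gmm_density_derivative

__all__ = ["BiasState", "bias_energy", "bias_forces", "update_bias",
           "DEFAULT_INCREMENT", "DEFAULT_WINDOW"]

logger = logging.getLogger(__name__)

#: bias increment between consecutive replicas, in system energy units
DEFAULT_INCREMENT = 4.0
#: sliding-window length for the density refit, in intervals
DEFAULT_WINDOW = 10


@dataclass
class BiasState:
    """Bias of one replica: its ladder position and the current CV models.

    ``models`` is empty during the unbiased first interval (interval_index 0).
    The bias energy of replica 1 is identically zero, and non-negative
    everywhere for every replica (density >= 0, Delta >= 0, r >= 1).
    """

    replica_index: int
    increment: float = DEFAULT_INCREMENT
    models: Dict[str, GMMModel] = field(default_factory=dict)
    interval_index: int = 0

    def __post_init__(self):
        if self.replica_index < 1:
            raise ValueError("replica_index is 1-based and must be >= 1")
        if self.increment < 0:
            raise ValueError("increment must be >= 0")

    @property
    def prefactor(self) -> float:
        """(r - 1) * Delta."""
        return (self.replica_index - 1) * self.increment

    def to_dict(self) -> dict:
        return {
            "replica_index": self.replica_index,
            "increment": self.increment,
            "interval_index": self.interval_index,
            "models": {name: m.to_dict() for name, m in self.models.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "BiasState":
        return cls(
            replica_index=d["replica_index"], increment=d["increment"],
            interval_index=d["interval_index"],
            models={k: GMMModel.from_dict(v) for k, v in d["models"].items()},
        )


def _check_models(bias: BiasState, cv_names: Sequence[str]) -> bool:
    """True if the bias is active; raises if models are missing after the
    unbiased first interval."""
    if bias.replica_index == 1 or bias.prefactor == 0.0:
        return False
    if not bias.models:
        if bias.interval_index == 0:
            return False
        raise ValueError(
            f"replica {bias.replica_index}: no bias models at interval "
            f"{bias.interval_index} (expected one per CV)"
        )
    missing = [n for n in cv_names if n not in bias.models]
    if missing:
        raise ValueError(
            f"replica {bias.replica_index}: missing bias model(s) for CV(s) {missing}"
        )
    return True


def bias_energy(bias: BiasState, cv_values: Dict[str, float]) -> float:
    """Total bias energy sum_CV (r-1) * Delta * p_CV(x_CV) at the given CV
    values; zero for the reference replica or during the first interval."""
    if not _check_models(bias, list(cv_values)):
        return 0.0
    return bias.prefactor * sum(
        gmm_density(bias.models[name], x) for name, x in cv_values.items()
    )


def bias_forces(bias: BiasState, coords: np.ndarray,
                cvs: Sequence[CVDefinition]) -> np.ndarray:
    """Per-particle bias force -dB/dx for one configuration (n, d).

    A CV whose geometry is singular (coincident COMs) contributes no force
    for this evaluation; a warning is logged.
    """
    coords = np.asarray(coords, dtype=float)
    f = np.zeros_like(coords)
    if not _check_models(bias, [c.name for c in cvs]):
        return f
    for cv in cvs:
        val = compute_cv_batch(coords[None], cv)[0]
        grad, singular = cv_gradient_batch(coords[None], cv)
        if singular[0]:
            logger.warning("CV %r singular; dropping its bias force", cv.name)
            continue
        dpdx = gmm_density_derivative(bias.models[cv.name], val)
        f -= bias.prefactor * dpdx * grad[0]
    return f


def batched_bias_forces(
    prefactors: np.ndarray,
    models: Dict[str, GMMModel],
    coords: np.ndarray,
    cvs: Sequence[CVDefinition],
    out: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Bias forces for a whole replica stack at once.

    All replicas share the same CV models (as produced by :func:`update_bias`)
    and differ only by their prefactor (r-1)*Delta; ``coords`` has shape
    (R, n, d) and ``prefactors`` shape (R,).  Used by the propagation hot
    loop.
    """
    f = np.zeros_like(coords) if out is None else out
    if out is not None:
        f[:] = 0.0
    if not models or not np.any(prefactors):
        return f
    for cv in cvs:
        vals = compute_cv_batch(coords, cv)
        grad, singular = cv_gradient_batch(coords, cv)
        dpdx = gmm_density_derivative(models[cv.name], vals)
        scale = np.where(singular, 0.0, -prefactors * dpdx)
        f += scale[:, None, None] * grad
    return f


def update_bias(
    history: Dict[str, List[np.ndarray]],
    cvs: Sequence[CVDefinition],
    K: int = 3,
    increment: float = DEFAULT_INCREMENT,
    n_replicas: int = 8,
    seed: int = 0,
    window: int = DEFAULT_WINDOW,
    previous: Optional[List[BiasState]] = None,
    interval_index: int = 1,
) -> List[BiasState]:
    """Refit the per-CV mixture models and build the next interval's biases.

    ``history`` maps CV name -> list of per-interval sample arrays (pooled
    over replicas); only the last ``window`` intervals enter the fit.  Every
    replica receives the same models scaled by its own (r-1)*Delta.  If a CV
    has too few samples its previous model is retained (warning logged).
    """
    fitted: Dict[str, GMMModel] = {}
    for cv in cvs:
        pools = history.get(cv.name, [])[-window:]
        samples = np.concatenate(pools) if pools else np.empty(0)
        try:
            fitted[cv.name] = fit_gmm(samples, K=K, seed=seed)
        except ValueError as err:
            prev_model = None
            if previous is not None:
                for b in previous:
                    if cv.name in b.models:
                        prev_model = b.models[cv.name]
                        break
            if prev_model is None:
                raise ValueError(
                    f"cannot build bias for CV {cv.name!r}: {err}"
                ) from None
            warnings.warn(
                f"CV {cv.name!r}: {err}; retaining previous model", stacklevel=2
            )
            fitted[cv.name] = prev_model
    return [
        BiasState(replica_index=r, increment=increment, models=dict(fitted),
                  interval_index=interval_index)
        for r in range(1, n_replicas + 1)
    ]
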