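"""Center-of-mass distance collective variables and their gradients.

A CV is the distance between the mass-weighted centers of two particle
groups (the convention of MD engines), or between one group's COM and a fixed
reference point — the latter is how 1D toy systems express "position |x|"
without an anchor particle.  Gradients are needed to turn a bias potential on
a CV into per-particle forces via the chain rule.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np

__all__ = ["AtomGroup", "CVDefinition", "compute_cv", "cv_gradient",
           "compute_cv_batch", "cv_gradient_batch", "SINGULAR_TOL"]

#: below this COM separation the CV direction is undefined and the gradient
#: is declared singular (bias force for that CV is dropped for the step)
SINGULAR_TOL = 1e-8


@dataclass(frozen=True)
class AtomGroup:
    """A named set of particles with masses, used as one COM endpoint."""

    name: str
    indices: np.ndarray
    masses: np.ndarray

    def __post_init__(self):
        idx = np.asarray(self.indices, dtype=int)
        m = np.asarray(self.masses, dtype=float)
        object.__setattr__(self, "indices", idx)
        object.__setattr__(self, "masses", m)
        if idx.ndim != 1 or len(idx) == 0:
            raise ValueError(f"group {self.name!r}: indices must be a non-empty 1D list")
        if len(np.unique(idx)) != len(idx):
            raise ValueError(f"group {self.name!r}: duplicate particle indices")
        if m.shape != idx.shape or m.sum() <= 0:
            raise ValueError(f"group {self.name!r}: need one positive mass per index")

    @property
    def total_mass(self) -> float:
        return float(self.masses.sum())

    @property
    def weights(self) -> np.ndarray:
        """Mass fractions m_i / M."""
        return self.masses / self.masses.sum()


@dataclass(frozen=True)
class CVDefinition:
    """COM distance between ``group_a`` and ``group_b`` (or a fixed point).

    When ``group_b`` is None the CV is |COM_a - reference_point|; the
    reference point carries no gradient.
    """

    name: str
    group_a: AtomGroup
    group_b: Optional[AtomGroup] = None
    reference_point: Optional[np.ndarray] = None

    def __post_init__(self):
        if self.group_b is not None:
            common = np.intersect1d(self.group_a.indices, self.group_b.indices)
            if len(common):
                raise ValueError(
                    f"CV {self.name!r}: groups overlap at particles {common.tolist()}"
                )
        if self.reference_point is not None:
            object.__setattr__(
                self, "reference_point", np.asarray(self.reference_point, dtype=float)
            )

    def max_index(self) -> int:
        m = int(self.group_a.indices.max())
        if self.group_b is not None:
            m = max(m, int(self.group_b.indices.max()))
        return m


def _com(coords: np.ndarray, group: AtomGroup) -> np.ndarray:
    """Mass-weighted COM for batched coords (..., n, d) -> (..., d)."""
    return np.einsum("...nd,n->...d", coords[..., group.indices, :], group.weights)


def _separation(coords: np.ndarray, cv: CVDefinition) -> np.ndarray:
    ca = _com(coords, cv.group_a)
    if cv.group_b is not None:
        cb = _com(coords, cv.group_b)
    else:
        ref = (np.zeros(coords.shape[-1]) if cv.reference_point is None
               else cv.reference_point)
        cb = np.broadcast_to(ref, ca.shape)
    return ca - cb


def compute_cv_batch(coords: np.ndarray, cv: CVDefinition) -> np.ndarray:
    """CV value for batched coordinates (..., n, d) -> (...)."""
    if coords.shape[-2] <= cv.max_index():
        raise IndexError(
            f"CV {cv.name!r} references particle {cv.max_index()} but coordinates "
            f"have only {coords.shape[-2]} particles"
        )
    sep = _separation(coords, cv)
    return np.sqrt(np.sum(sep * sep, axis=-1))


def compute_cv(coords: np.ndarray, cv: CVDefinition) -> float:
    """|COM_a - COM_b| for a single configuration (n, d)."""
    return float(compute_cv_batch(np.asarray(coords, dtype=float)[None], cv)[0])


def cv_gradient_batch(coords: np.ndarray, cv: CVDefinition):
    """Gradient of the CV w.r.t. every coordinate, batched.

    Returns ``(grad, singular)`` where ``grad`` has the shape of ``coords``
    and ``singular`` is a boolean mask (batch shape) marking configurations
    whose COM separation is below :data:`SINGULAR_TOL`; their gradient rows
    are zeroed and callers should drop the corresponding bias force.
    """
    coords = np.asarray(coords, dtype=float)
    if coords.shape[-2] <= cv.max_index():
        raise IndexError(f"CV {cv.name!r}: particle index out of range")
    sep = _separation(coords, cv)
    d = np.sqrt(np.sum(sep * sep, axis=-1))
    singular = d < SINGULAR_TOL
    dsafe = np.where(singular, 1.0, d)
    unit = sep / dsafe[..., None]
    unit = np.where(singular[..., None], 0.0, unit)
    grad = np.zeros_like(coords)
    grad[..., cv.group_a.indices, :] = unit[..., None, :] * cv.group_a.weights[:, None]
    if cv.group_b is not None:
        grad[..., cv.group_b.indices, :] = -unit[..., None, :] * cv.group_b.weights[:, None]
    return grad, singular


def cv_gradient(coords: np.ndarray, cv: CVDefinition) -> np.ndarray:
    """Analytic CV gradient for one configuration (n, d).

    Raises ``FloatingPointError`` when the COM separation is below
    :data:`SINGULAR_TOL` (direction undefined).
    """
    grad, singular = cv_gradient_batch(np.asarray(coords, dtype=float)[None], cv)
    if singular[0]:
        raise FloatingPointError(
            f"CV {cv.name!r} is singular (COM separation < {SINGULAR_TOL})"
        )
    return grad[0]


def make_com_cvs(groups: dict, pairs: Sequence, masses: np.ndarray) -> list:
    """Build CVDefinitions from a {name: indices} group mapping and a list of
    (cv_name, group_a, group_b_or_None) pairs; ``group_b`` None means distance
    to the origin."""
    cvs = []
    masses = np.asarray(masses, dtype=float)
    def grp(name):
        idx = np.asarray(groups[name], dtype=int)
        return AtomGroup(name=name, indices=idx, masses=masses[idx])
    for entry in pairs:
        cv_name, a, b = entry
        cvs.append(CVDefinition(name=cv_name, group_a=grp(a),
                                group_b=None if b is None else grp(b)))
    return cvs
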