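"""Desk-scale simulable systems and a Langevin propagator.

Provides analytic potentials (harmonic well, 1D quartic double well, the 2D
Mueller-Brown surface) and a coarse-grained domain bead model whose domains
interact through a double-well distance potential, so that center-of-mass
distance collective variables exhibit metastability.  All systems use reduced
units (kT = 1 by default) and are propagated with a BAOAB Langevin splitting
integrator whose stationary distribution is the Boltzmann distribution of the
total (potential + bias) energy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional

import numpy as np

__all__ = [
    "Potential",
    "HarmonicWell",
    "DoubleWell1D",
    "MuellerBrown",
    "BeadModel",
    "SystemSpec",
    "Frame",
    "make_harmonic",
    "make_double_well",
    "make_muller_brown",
    "make_domain_bead_model",
    "langevin_step",
    "simulate",
]


class Potential:
    """Base class: potentials evaluate energy/forces on batched coordinates.

    Coordinates have shape ``(..., n_particles, dim)``; ``energy`` returns
    shape ``(...)`` and ``forces`` the input shape.
    """

    name: str = "potential"

    def energy(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def forces(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError

    def params(self) -> dict:
        return {}


class HarmonicWell(Potential):
    """U(x) = 1/2 k |x - x0|^2 summed over particles."""

    name = "harmonic"

    def __init__(self, k: float = 1.0, center: float = 0.0):
        if k <= 0:
            raise ValueError("force constant k must be positive")
        self.k = float(k)
        self.center = float(center)

    def energy(self, x):
        d = x - self.center
        return 0.5 * self.k * np.sum(d * d, axis=(-2, -1))

    def forces(self, x):
        return -self.k * (x - self.center)

    def params(self):
        return {"k": self.k, "center": self.center}


class DoubleWell1D(Potential):
    """Symmetric quartic double well U(x) = h ((x/a)^2 - 1)^2.

    Minima at x = +-a with U = 0; barrier U(0) = h.
    """

    name = "double_well"

    def __init__(self, barrier_height: float, well_separation: float):
        if barrier_height <= 0 or well_separation <= 0:
            raise ValueError("barrier_height and well_separation must be positive")
        self.h = float(barrier_height)
        self.a = float(well_separation)

    def energy(self, x):
        u = (x[..., 0, 0] / self.a) ** 2 - 1.0
        return self.h * u * u

    def forces(self, x):
        xx = x[..., 0, 0]
        g = 4.0 * self.h * xx * (xx * xx / self.a**2 - 1.0) / self.a**2
        f = np.zeros_like(x)
        f[..., 0, 0] = -g
        return f

    def params(self):
        return {"barrier_height": self.h, "well_separation": self.a}


class MuellerBrown(Potential):
    """The classic 2D Mueller-Brown surface (one particle, dim 2), scaled.

    ``scale`` multiplies the canonical energy so that barrier heights can be
    matched to kT = 1 conditions (the canonical surface spans ~150 units).
    """

    name = "muller_brown"

    _A = np.array([-200.0, -100.0, -170.0, 15.0])
    _a = np.array([-1.0, -1.0, -6.5, 0.7])
    _b = np.array([0.0, 0.0, 11.0, 0.6])
    _c = np.array([-10.0, -10.0, -6.5, 0.7])
    _x0 = np.array([1.0, 0.0, -0.5, -1.0])
    _y0 = np.array([0.0, 0.5, 1.5, 1.0])

    def __init__(self, scale: float = 0.05):
        if scale <= 0:
            raise ValueError("scale must be positive")
        self.scale = float(scale)

    def _terms(self, x):
        dx = x[..., 0, 0, None] - self._x0
        dy = x[..., 0, 1, None] - self._y0
        e = self._A * np.exp(self._a * dx**2 + self._b * dx * dy + self._c * dy**2)
        return e, dx, dy

    def energy(self, x):
        e, _, _ = self._terms(x)
        return self.scale * e.sum(axis=-1)

    def forces(self, x):
        e, dx, dy = self._terms(x)
        gx = (e * (2 * self._a * dx + self._b * dy)).sum(axis=-1)
        gy = (e * (self._b * dx + 2 * self._c * dy)).sum(axis=-1)
        f = np.zeros_like(x)
        f[..., 0, 0] = -self.scale * gx
        f[..., 0, 1] = -self.scale * gy
        return f

    def params(self):
        return {"scale": self.scale}


class BeadModel(Potential):
    """Bead clusters ("domains") with stiff intra-domain harmonic bonds and
    double-well potentials acting on inter-domain mass-weighted COM distances.

    Parameters
    ----------
    bonds : (n_bonds, 2) int array of particle pairs.
    bond_r0 : equilibrium length per bond.
    bond_k : harmonic force constant (shared).
    groups : list of index arrays, one per domain.
    masses : per-particle masses (for the COM definition).
    pair_potentials : list of ((gi, gj), DoubleWellDistance-params) entries —
        each entry is ``(pair, (h, d1, d2))`` putting double-well minima at
        COM distances d1 and d2 with barrier h between them.
    """

    name = "bead_model"

    def __init__(self, bonds, bond_r0, bond_k, groups, masses, pair_potentials):
        self.bonds = np.asarray(bonds, dtype=int)
        self.bond_r0 = np.asarray(bond_r0, dtype=float)
        self.bond_k = float(bond_k)
        self.groups = [np.asarray(g, dtype=int) for g in groups]
        self.masses = np.asarray(masses, dtype=float)
        self.pair_potentials = [
            ((int(i), int(j)), (float(h), float(d1), float(d2)))
            for (i, j), (h, d1, d2) in pair_potentials
        ]

    # double well in distance d with minima at d1 < d2:
    # U(d) = h * (((d - c)/w)^2 - 1)^2, c = (d1+d2)/2, w = (d2-d1)/2
    @staticmethod
    def _dw(d, h, d1, d2):
        c, w = 0.5 * (d1 + d2), 0.5 * (d2 - d1)
        u = ((d - c) / w) ** 2 - 1.0
        return h * u * u

    @staticmethod
    def _dw_deriv(d, h, d1, d2):
        c, w = 0.5 * (d1 + d2), 0.5 * (d2 - d1)
        s = (d - c) / w
        return 4.0 * h * s * (s * s - 1.0) / w

    def _com(self, x, g):
        m = self.masses[g]
        return np.einsum("...nd,n->...d", x[..., g, :], m) / m.sum()

    def energy(self, x):
        i, j = self.bonds[:, 0], self.bonds[:, 1]
        dvec = x[..., i, :] - x[..., j, :]
        r = np.sqrt(np.sum(dvec * dvec, axis=-1))
        e = 0.5 * self.bond_k * np.sum((r - self.bond_r0) ** 2, axis=-1)
        for (gi, gj), (h, d1, d2) in self.pair_potentials:
            dd = self._com(x, self.groups[gi]) - self._com(x, self.groups[gj])
            d = np.sqrt(np.sum(dd * dd, axis=-1))
            e = e + self._dw(d, h, d1, d2)
        return e

    def forces(self, x):
        f = np.zeros_like(x)
        i, j = self.bonds[:, 0], self.bonds[:, 1]
        dvec = x[..., i, :] - x[..., j, :]
        r = np.sqrt(np.sum(dvec * dvec, axis=-1))
        fb = (-self.bond_k * (r - self.bond_r0) / r)[..., None] * dvec
        np.add.at(f, (..., i, slice(None)), fb)
        np.add.at(f, (..., j, slice(None)), -fb)
        for (gi, gj), (h, d1, d2) in self.pair_potentials:
            ga, gb = self.groups[gi], self.groups[gj]
            dd = self._com(x, ga) - self._com(x, gb)
            d = np.sqrt(np.sum(dd * dd, axis=-1))
            dU = self._dw_deriv(d, h, d1, d2)
            unit = dd / d[..., None]
            wa = self.masses[ga] / self.masses[ga].sum()
            wb = self.masses[gb] / self.masses[gb].sum()
            contrib = (-dU)[..., None] * unit
            f[..., ga, :] += contrib[..., None, :] * wa[:, None]
            f[..., gb, :] -= contrib[..., None, :] * wb[:, None]
        return f

    def params(self):
        return {
            "n_bonds": int(len(self.bonds)),
            "bond_k": self.bond_k,
            "pair_potentials": self.pair_potentials,
        }


@dataclass
class SystemSpec:
    """A simulable system: potential plus thermodynamic/integration state.

    Reduced units throughout: energies in units of the thermal energy scale,
    masses and lengths O(1).
    """

    n_particles: int
    dim: int
    masses: np.ndarray
    potential: Potential
    initial_coordinates: np.ndarray
    kT: float = 1.0
    friction: float = 1.0
    dt: float = 0.01
    groups: dict = field(default_factory=dict)  # name -> particle index array

    def __post_init__(self):
        self.masses = np.atleast_1d(np.asarray(self.masses, dtype=float))
        self.initial_coordinates = np.asarray(self.initial_coordinates, dtype=float).reshape(
            self.n_particles, self.dim
        )
        if self.n_particles < 1:
            raise ValueError("n_particles must be >= 1")
        if not (1 <= self.dim <= 3):
            raise ValueError("dim must be 1, 2 or 3")
        if self.masses.shape != (self.n_particles,) or np.any(self.masses <= 0):
            raise ValueError("masses must be positive, one per particle")
        if self.dt <= 0 or self.kT < 0 or self.friction < 0:
            raise ValueError("dt must be > 0; kT and friction must be >= 0")
        e0 = float(self.potential.energy(self.initial_coordinates[None])[0])
        if not np.isfinite(e0):
            raise ValueError("potential energy not finite at initial coordinates")


@dataclass
class Frame:
    """One saved state of a trajectory."""

    step_index: int
    coordinates: np.ndarray
    potential_energy: float
    bias_energy: float = 0.0
    velocities: Optional[np.ndarray] = None


def make_harmonic(k: float = 1.0, kT: float = 1.0, friction: float = 1.0,
                  dt: float = 0.01) -> SystemSpec:
    """One particle in a 1D harmonic well U = 1/2 k x^2."""
    return SystemSpec(
        n_particles=1, dim=1, masses=np.ones(1), potential=HarmonicWell(k=k),
        initial_coordinates=np.zeros((1, 1)), kT=kT, friction=friction, dt=dt,
        groups={"particle": np.array([0])},
    )


def make_double_well(barrier_height: float, well_separation: float,
                     kT: float = 1.0, friction: float = 1.0,
                     dt: float = 0.01) -> SystemSpec:
    """One particle in the 1D quartic double well, started in the right well."""
    pot = DoubleWell1D(barrier_height, well_separation)
    x0 = np.array([[well_separation]])
    return SystemSpec(
        n_particles=1, dim=1, masses=np.ones(1), potential=pot,
        initial_coordinates=x0, kT=kT, friction=friction, dt=dt,
        groups={"particle": np.array([0])},
    )


def make_muller_brown(scale: float = 0.05, kT: float = 1.0, friction: float = 2.0,
                      dt: float = 0.005) -> SystemSpec:
    """One particle on the (scaled) 2D Mueller-Brown surface, started in the
    deepest minimum."""
    return SystemSpec(
        n_particles=1, dim=2, masses=np.ones(1), potential=MuellerBrown(scale),
        initial_coordinates=np.array([[-0.558, 1.442]]), kT=kT,
        friction=friction, dt=dt, groups={"particle": np.array([0])},
    )


def make_domain_bead_model(
    n_domains: int = 2,
    beads_per_domain: int = 4,
    inter_domain: tuple = (4.0, 4.0, 8.0),
    seed: int = 0,
    bond_k: float = 100.0,
    jitter: float = 0.35,
    min_separation: float = 0.2,
    kT: float = 1.0,
    friction: float = 1.0,
    dt: float = 0.005,
) -> SystemSpec:
    """Coarse-grained multi-domain bead model.

    Each domain is a near-rigid cluster of beads (all intra-domain pairs
    bonded harmonically at their initial lengths).  Consecutive domain pairs
    interact through a double-well potential on their mass-weighted COM
    distance: ``inter_domain = (barrier, d_min1, d_min2)`` puts minima at COM
    separations d_min1 and d_min2.  This emulates two protein lobes that
    toggle between a closed and an open arrangement, giving the COM-distance
    collective variables genuine metastable states.

    Construction is deterministic given ``seed``; beads are placed on a
    jittered tetrahedral/lattice motif per domain and initial placements with
    any bead pair closer than ``min_separation`` are rejected.
    """
    if n_domains < 2:
        raise ValueError("n_domains must be >= 2")
    if beads_per_domain < 2:
        raise ValueError("beads_per_domain must be >= 2")
    h, d1, d2 = map(float, inter_domain)
    if h <= 0 or d1 <= 0 or d2 <= d1:
        raise ValueError("inter_domain must be (barrier>0, d1>0, d2>d1)")

    rng = np.random.default_rng(seed)
    n = n_domains * beads_per_domain
    # local lattice motif inside a domain, side 1
    side = int(np.ceil(beads_per_domain ** (1.0 / 3.0)))
    motif = np.array(
        [[i % side, (i // side) % side, i // side**2] for i in range(beads_per_domain)],
        dtype=float,
    )
    motif -= motif.mean(axis=0)
    coords = np.zeros((n, 3))
    groups = {}
    for d in range(n_domains):
        sl = slice(d * beads_per_domain, (d + 1) * beads_per_domain)
        center = np.array([d * d1, 0.0, 0.0])  # start in the closed minimum
        coords[sl] = center + motif + jitter * rng.standard_normal(motif.shape)
        groups[f"domain_{d}"] = np.arange(sl.start, sl.stop)

    diff = coords[:, None, :] - coords[None, :, :]
    dist = np.sqrt((diff**2).sum(-1)) + np.eye(n) * 1e9
    if dist.min() < min_separation:
        raise ValueError(
            f"overlapping bead placement (min pair distance {dist.min():.3g} < "
            f"{min_separation}); change seed or jitter"
        )

    bonds, r0 = [], []
    for d in range(n_domains):
        idx = groups[f"domain_{d}"]
        for a in range(len(idx)):
            for b in range(a + 1, len(idx)):
                bonds.append((idx[a], idx[b]))
                r0.append(np.linalg.norm(coords[idx[a]] - coords[idx[b]]))
    masses = np.ones(n)
    pair_pots = [((d, d + 1), (h, d1, d2)) for d in range(n_domains - 1)]
    pot = BeadModel(np.array(bonds), np.array(r0), bond_k,
                    [groups[f"domain_{d}"] for d in range(n_domains)],
                    masses, pair_pots)
    return SystemSpec(
        n_particles=n, dim=3, masses=masses, potential=pot,
        initial_coordinates=coords, kT=kT, friction=friction, dt=dt,
        groups=groups,
    )


def _baoab_coeffs(spec: SystemSpec):
    a = np.exp(-spec.friction * spec.dt)
    b = np.sqrt(spec.kT * (1.0 - a * a) / spec.masses)  # per-particle sigma
    return a, b[:, None]


def _baoab_block(x, v, n_steps, spec, force_fn, noise):
    """Advance batched states ``x, v`` of shape (R, n, d) by ``n_steps`` BAOAB
    steps.  ``noise[t]`` supplies the standard normals for step t (shape
    (R, n, d)); ``force_fn(x) -> total force``.  Mutates and returns x, v."""
    dt = spec.dt
    minv = (1.0 / spec.masses)[:, None]
    a, b = _baoab_coeffs(spec)
    f = force_fn(x)
    for t in range(n_steps):
        v += 0.5 * dt * f * minv
        x += 0.5 * dt * v
        v *= a
        v += b * noise[t]
        x += 0.5 * dt * v
        f = force_fn(x)
        v += 0.5 * dt * f * minv
        if not np.isfinite(f).all() or not np.isfinite(x).all():
            bad = "force" if not np.isfinite(f).all() else "coordinates"
            raise FloatingPointError(
                f"non-finite {bad} encountered at propagation step {t}"
            )
    return x, v, f


def langevin_step(state: Frame, spec: SystemSpec,
                  extra_force: Optional[np.ndarray] = None,
                  rng: Optional[np.random.Generator] = None) -> Frame:
    """Advance one frame by a single BAOAB Langevin step.

    ``extra_force`` (e.g. a bias force) is added to the potential force; pass
    ``None`` or zeros when unbiased.  The stationary distribution of the
    iterated map is Boltzmann at ``spec.kT`` for the total energy.
    Deterministic given the generator state.
    """
    if rng is None:
        rng = np.random.default_rng(0)
    x = np.array(state.coordinates, dtype=float, copy=True)[None]
    v = (np.zeros_like(x) if state.velocities is None
         else np.array(state.velocities, dtype=float, copy=True)[None])
    ef = 0.0 if extra_force is None else np.asarray(extra_force, dtype=float)
    if extra_force is not None and np.shape(ef) != x.shape[1:]:
        raise ValueError("extra_force shape must match coordinates")
    if extra_force is not None and not np.isfinite(ef).all():
        raise FloatingPointError(
            f"non-finite extra force at step {state.step_index}"
        )

    def force_fn(xx):
        return spec.potential.forces(xx) + ef

    noise = rng.standard_normal((1, *x.shape[1:]))[None]
    try:
        x, v, _ = _baoab_block(x, v, 1, spec, force_fn, noise)
    except FloatingPointError as err:
        raise FloatingPointError(f"{err} (frame step_index={state.step_index})") from None
    pe = float(spec.potential.energy(x)[0])
    return Frame(
        step_index=state.step_index + 1, coordinates=x[0], potential_energy=pe,
        bias_energy=0.0, velocities=v[0],
    )


def simulate(
    spec: SystemSpec,
    n_steps: int,
    seed: int = 0,
    save_period: int = 1,
    x0: Optional[np.ndarray] = None,
    extra_force_fn: Optional[Callable[[np.ndarray], np.ndarray]] = None,
    block: int = 1000,
) -> np.ndarray:
    """Plain (single-replica) Langevin run; returns saved coordinates with
    shape ``(n_saved, n_particles, dim)``.

    Noise is drawn from ``default_rng(seed)`` in fixed order, so runs are
    bitwise reproducible.
    """
    rng = np.random.default_rng(seed)
    x = np.array(spec.initial_coordinates if x0 is None else x0,
                 dtype=float, copy=True)[None]
    v = np.zeros_like(x)

    fast = (
        extra_force_fn is None
        and spec.n_particles == 1 and spec.dim == 1
        and float(spec.masses[0]) == 1.0
        and isinstance(spec.potential, (DoubleWell1D, HarmonicWell))
    )
    if fast:
        from ._kernels import ladder_block

        pot = spec.potential
        if isinstance(pot, DoubleWell1D):
            pot_kind, p1, p2 = 0, pot.h, pot.a**2
        else:
            pot_kind, p1, p2 = 1, pot.k, pot.center
        a = np.exp(-spec.friction * spec.dt)
        b = float(np.sqrt(spec.kT * (1.0 - a * a)))
        empty = np.empty(0)
        prefs = np.zeros(1)

        def advance(nn):
            ladder_block(x[:, 0, 0], v[:, 0, 0], pot_kind, float(p1), float(p2),
                         prefs, empty, empty, empty, float(a), b, spec.dt, nn[:, :, 0, 0])
    else:
        if extra_force_fn is None:
            force_fn = spec.potential.forces
        else:
            def force_fn(xx):
                return spec.potential.forces(xx) + extra_force_fn(xx)

        def advance(nn):
            _baoab_block(x, v, nn.shape[0], spec, force_fn, nn)

    out = np.empty((n_steps // save_period, spec.n_particles, spec.dim))
    nsave = 0
    done = 0
    while done < n_steps:
        m = min(block, n_steps - done)
        # save points inside this block, relative step offsets
        offsets = [s - done for s in range(done + 1, done + m + 1) if s % save_period == 0]
        noise = rng.standard_normal((m, *x.shape[1:]))[:, None]
        # step through sub-segments between saves
        prev = 0
        for off in offsets:
            advance(noise[prev:off])
            out[nsave] = x[0]
            nsave += 1
            prev = off
        if prev < m:
            advance(noise[prev:m])
        done += m
    if fast and not np.isfinite(x).all():
        raise FloatingPointError("non-finite coordinates during simulation")
    return out[:nsave]
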