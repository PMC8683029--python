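"""Adaptive Hamiltonian replica-exchange driver.

The campaign runs a fixed number of *intervals*, each a cycle of

  1. replica-exchange sampling: every replica is propagated with its own bias
     force added to the physical force; configuration swaps between adjacent
     replicas are attempted on a fixed cadence with a Metropolis criterion;
  2. CV analysis: the saved CV values of all replicas are pooled;
  3. bias update: a fresh Gaussian-mixture density is fitted to the pooled
     samples of the last ``window`` intervals and becomes the next interval's
     bias (scaled per replica).

The first interval runs unbiased to seed the density estimate.  All replicas
share one temperature and one unbiased Hamiltonian, so the Metropolis
exponent for a swap reduces to bias-energy differences:

    Delta = [B_i(xi(x_j)) + B_j(xi(x_i))] - [B_i(xi(x_i)) + B_j(xi(x_j))]

with xi(x) the CV values of configuration x; the swap is accepted with
probability min(1, exp(-Delta/kT)).  Replica 1 is the fixed unbiased
reference slot; configurations (coordinates and velocities) move between
slots, so the reference slot's trajectory samples the plain Boltzmann
distribution and is the only one analyzed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .bias import (BiasState, DEFAULT_INCREMENT, DEFAULT_WINDOW,
                   batched_bias_forces, bias_energy, update_bias)
from .cv import CVDefinition, compute_cv_batch
from .gmm import gmm_density
from .systems import (DoubleWell1D, Frame, HarmonicWell, SystemSpec,
                      _baoab_block, _baoab_coeffs)
from . import io as aio
from ._kernels import ladder_block

__all__ = ["ScheduleConfig", "ExchangeRecord", "EnsembleState",
           "attempt_exchange", "run_interval", "run_campaign", "CampaignResult"]

logger = logging.getLogger(__name__)


@dataclass
class ScheduleConfig:
    """Batch parameters of one campaign.

    The defaults mirror the reference protocol's cadence ratios as step
    ratios: exchanges every 80 steps, 10,000-step intervals, a 10-interval
    sliding window (the analogue of exchanging every 8 ps with 1-ns intervals
    and a 10-ns window), and 8 replicas with increment 4 energy units.
    """

    n_replicas: int = 8
    steps_per_interval: int = 10_000
    exchange_period: int = 80
    n_intervals: int = 20
    window: int = DEFAULT_WINDOW
    save_period: Optional[int] = None          # default: exchange_period
    reference_save_period: Optional[int] = None  # default: save_period
    seed: int = 0
    K: int = 3
    increment: float = DEFAULT_INCREMENT
    max_fit_replica: Optional[int] = None  # pool only replicas <= this in fits

    def __post_init__(self):
        if self.save_period is None:
            self.save_period = self.exchange_period
        if self.reference_save_period is None:
            self.reference_save_period = self.save_period
        if self.n_replicas < 1:
            raise ValueError("n_replicas must be >= 1")
        if self.steps_per_interval % self.exchange_period:
            raise ValueError("exchange_period must divide steps_per_interval")
        if self.exchange_period % self.save_period:
            raise ValueError("save_period must divide exchange_period")
        if self.save_period % self.reference_save_period:
            raise ValueError("reference_save_period must divide save_period")
        if self.n_intervals < 1 or self.window < 1 or self.K < 1:
            raise ValueError("n_intervals, window and K must be >= 1")
        if self.increment < 0:
            raise ValueError("increment must be >= 0")


@dataclass
class ExchangeRecord:
    """One exchange attempt between adjacent replicas (1-based indices)."""

    step: int
    pair: tuple
    delta: float  # dimensionless Metropolis exponent argument Delta/kT
    accepted: bool


@dataclass
class EnsembleState:
    """Full mutable state of a campaign."""

    coords: np.ndarray        # (R, n, d)
    velocities: np.ndarray    # (R, n, d)
    biases: List[BiasState]
    cvs: List[CVDefinition]
    interval: int = 0
    step: int = 0
    n_attempt_rounds: int = 0
    cv_history: Dict[str, List[np.ndarray]] = field(default_factory=dict)
    cv_steps: List[np.ndarray] = field(default_factory=list)
    exchange_log: List[ExchangeRecord] = field(default_factory=list)
    #: per-interval arrays of reference-replica coordinates
    #: (n_saves, n_particles, dim)
    reference_positions: List[np.ndarray] = field(default_factory=list)
    bias_snapshots: List[dict] = field(default_factory=list)
    rngs: List[np.random.Generator] = field(default_factory=list)
    exchange_rng: Optional[np.random.Generator] = None

    @classmethod
    def initialize(cls, spec: SystemSpec, cvs: Sequence[CVDefinition],
                   schedule: ScheduleConfig) -> "EnsembleState":
        R = schedule.n_replicas
        ss = np.random.SeedSequence(schedule.seed)
        children = ss.spawn(R + 2)
        rngs = [np.random.default_rng(c) for c in children[:R]]
        exchange_rng = np.random.default_rng(children[R])
        coords = np.tile(spec.initial_coordinates[None], (R, 1, 1)).astype(float)
        vels = np.zeros_like(coords)
        biases = [BiasState(replica_index=r + 1, increment=schedule.increment,
                            interval_index=0) for r in range(R)]
        return cls(coords=coords, velocities=vels, biases=biases,
                   cvs=list(cvs), cv_history={cv.name: [] for cv in cvs},
                   rngs=rngs, exchange_rng=exchange_rng)


def attempt_exchange(
    state_i: Frame,
    state_j: Frame,
    bias_i: BiasState,
    bias_j: BiasState,
    cvs: Sequence[CVDefinition],
    kT: float,
    rng: np.random.Generator,
) -> ExchangeRecord:
    """Metropolis test for swapping two configurations between bias levels.

    Both replicas share the temperature and the unbiased Hamiltonian, so only
    bias energies enter the exponent.  The caller performs the swap when
    ``accepted`` is True; the record is returned either way.
    """
    xi_i = {cv.name: compute_cv_batch(np.asarray(state_i.coordinates)[None], cv)[0]
            for cv in cvs}
    xi_j = {cv.name: compute_cv_batch(np.asarray(state_j.coordinates)[None], cv)[0]
            for cv in cvs}
    delta = (bias_energy(bias_i, xi_j) + bias_energy(bias_j, xi_i)
             - bias_energy(bias_i, xi_i) - bias_energy(bias_j, xi_j))
    d = delta / kT
    accepted = bool(rng.random() < np.exp(-min(d, 700.0)))
    return ExchangeRecord(
        step=state_i.step_index,
        pair=(bias_i.replica_index, bias_j.replica_index),
        delta=float(d), accepted=accepted,
    )


def _shared_models(biases: List[BiasState]) -> Dict[str, "object"]:
    """The CV models shared by the ladder (empty during interval 0)."""
    for b in biases:
        if b.replica_index > 1 and b.models:
            return b.models
    return {}


def _exchange_sweep(ens: EnsembleState, spec: SystemSpec,
                    parity: int, fast_cv: bool = False) -> None:
    """One round of adjacent-pair swap attempts at the given parity.

    All replicas share the CV models (update_bias installs the same fit
    everywhere), so B_r(x) = pref_r * P(x) with P(x) = sum_CV p_CV(x_CV) and
    the pair exponent reduces to (pref_i - pref_j) (P(x_j) - P(x_i)).
    """
    R = len(ens.biases)
    models = _shared_models(ens.biases)
    if models:
        P = np.zeros(R)
        if fast_cv:
            d = np.abs(ens.coords[:, 0, 0])
            for cv in ens.cvs:
                P += gmm_density(models[cv.name], d)
        else:
            for cv in ens.cvs:
                P += gmm_density(models[cv.name], compute_cv_batch(ens.coords, cv))
    else:
        P = np.zeros(R)
    prefs = np.array([b.prefactor for b in ens.biases])
    for i in range(parity, R - 1, 2):
        delta = (prefs[i] - prefs[i + 1]) * (P[i + 1] - P[i]) / spec.kT
        accepted = bool(ens.exchange_rng.random() < np.exp(-min(delta, 700.0)))
        ens.exchange_log.append(ExchangeRecord(
            step=ens.step, pair=(i + 1, i + 2), delta=float(delta),
            accepted=accepted))
        if accepted:
            ens.coords[[i, i + 1]] = ens.coords[[i + 1, i]]
            ens.velocities[[i, i + 1]] = ens.velocities[[i + 1, i]]
            P[[i, i + 1]] = P[[i + 1, i]]


def _ladder_params(spec: SystemSpec, cvs, models):
    """Parameters for the fused 1D propagation kernel, or None.

    Applicable to single-particle 1D systems with unit mass whose CVs are all
    origin-referenced COM distances (|x|); the mixture components of all CVs
    are concatenated since the bias is a sum over CVs.
    """
    pot = spec.potential
    ok = (
        spec.n_particles == 1
        and spec.dim == 1
        and float(spec.masses[0]) == 1.0
        and isinstance(pot, (DoubleWell1D, HarmonicWell))
        and all(cv.group_b is None
                and (cv.reference_point is None or not cv.reference_point.any())
                for cv in cvs)
    )
    if not ok:
        return None
    if isinstance(pot, DoubleWell1D):
        pot_kind, p1, p2 = 0, pot.h, pot.a**2
    else:
        pot_kind, p1, p2 = 1, pot.k, pot.center
    mus, sigs, amps = [], [], []
    for cv in cvs:
        if models and cv.name in models:
            m = models[cv.name]
            mus.append(m.means)
            sigs.append(m.widths)
            amps.append(m.weights / (m.widths * np.sqrt(2.0 * np.pi)))
    cat = (lambda parts: np.ascontiguousarray(np.concatenate(parts))
           if parts else np.empty(0))
    return {
        "pot_kind": pot_kind, "p1": float(p1), "p2": float(p2),
        "mus": cat(mus), "sigs": cat(sigs), "amps": cat(amps),
    }


def _make_stepper(spec: SystemSpec, ens: "EnsembleState", models, prefactors):
    """Return ``step(noise_block)`` advancing the whole replica stack in
    place by ``noise_block.shape[0]`` BAOAB steps."""
    params = _ladder_params(spec, ens.cvs, models)
    if params is not None:
        xf = ens.coords[:, 0, 0]
        vf = ens.velocities[:, 0, 0]
        a_coef = float(np.exp(-spec.friction * spec.dt))
        b_coef = float(np.sqrt(spec.kT * (1.0 - a_coef**2)))
        prefs = np.ascontiguousarray(prefactors, dtype=float)

        def step(noise):
            ladder_block(xf, vf, params["pot_kind"], params["p1"], params["p2"],
                         prefs, params["mus"], params["sigs"], params["amps"],
                         a_coef, b_coef, spec.dt,
                         np.ascontiguousarray(noise[:, :, 0, 0]))

        return step

    pot = spec.potential
    if not models:
        force_fn = pot.forces
    else:
        def force_fn(x):
            return pot.forces(x) + batched_bias_forces(prefactors, models, x,
                                                       ens.cvs)

    def step(noise):
        _baoab_block(ens.coords, ens.velocities, noise.shape[0], spec,
                     force_fn, noise)

    return step


def run_interval(ensemble: EnsembleState, spec: SystemSpec,
                 schedule: ScheduleConfig) -> EnsembleState:
    """Advance the ensemble by one full interval and refit the bias.

    Each replica runs ``steps_per_interval`` Langevin steps with its bias
    force applied at every step; adjacent-pair exchanges are attempted every
    ``exchange_period`` steps with alternating even/odd pairing; CV values
    are recorded every ``save_period`` steps and pooled into the history;
    finally the Gaussian-mixture models are refitted on the sliding window
    and installed as the next interval's biases.
    """
    ens = ensemble
    R = len(ens.biases)
    models = _shared_models(ens.biases)
    prefactors = np.array([b.prefactor for b in ens.biases])
    if not models:
        prefactors = np.zeros(R)
    stepper = _make_stepper(spec, ens, models, prefactors)

    n_seg = schedule.steps_per_interval // schedule.exchange_period
    saves_per_seg = schedule.exchange_period // schedule.save_period
    n_saves = n_seg * saves_per_seg
    cv_block = {cv.name: np.empty((n_saves, R)) for cv in ens.cvs}
    step_block = np.empty(n_saves, dtype=int)
    isave = 0
    npart, dim = ens.coords.shape[1], ens.coords.shape[2]
    fast_cv = _ladder_params(spec, ens.cvs, None) is not None

    # pre-draw the whole interval's noise from the per-replica streams
    noise = np.empty((schedule.steps_per_interval, R, npart, dim))
    for r in range(R):
        noise[:, r] = ens.rngs[r].standard_normal(
            (schedule.steps_per_interval, npart, dim))

    ref_buf = np.empty((schedule.steps_per_interval
                        // schedule.reference_save_period, npart, dim))
    iref = 0
    for seg in range(n_seg):
        seg0 = seg * schedule.exchange_period
        done = 0
        while done < schedule.exchange_period:
            m = schedule.reference_save_period
            try:
                stepper(noise[seg0 + done:seg0 + done + m])
            except FloatingPointError as err:
                raise FloatingPointError(
                    f"replica propagation failed in interval {ens.interval} "
                    f"near step {ens.step + done}: {err}"
                ) from None
            done += m
            ens.step += m
            if ens.step % schedule.save_period == 0:
                if fast_cv:
                    for cv in ens.cvs:
                        cv_block[cv.name][isave] = np.abs(ens.coords[:, 0, 0])
                else:
                    for cv in ens.cvs:
                        cv_block[cv.name][isave] = compute_cv_batch(ens.coords, cv)
                step_block[isave] = ens.step
                isave += 1
            ref_buf[iref] = ens.coords[0]
            iref += 1
        if not np.isfinite(ens.coords).all():
            raise FloatingPointError(
                f"non-finite coordinates in interval {ens.interval} at step "
                f"{ens.step}; state dump: coords={ens.coords!r}"
            )
        if R > 1:
            _exchange_sweep(ens, spec, parity=ens.n_attempt_rounds % 2,
                            fast_cv=fast_cv)
            ens.n_attempt_rounds += 1

    for cv in ens.cvs:
        ens.cv_history[cv.name].append(cv_block[cv.name])
    ens.cv_steps.append(step_block)
    ens.reference_positions.append(ref_buf)

    # bias refit on the sliding window (pooled over replicas)
    fit_pool = {}
    for cv in ens.cvs:
        arrs = ens.cv_history[cv.name][-schedule.window:]
        if schedule.max_fit_replica is not None:
            arrs = [a[:, :schedule.max_fit_replica] for a in arrs]
        fit_pool[cv.name] = [a.ravel() for a in arrs]
    ens.interval += 1
    # fixed fit seed: consecutive refits differ only through the data window,
    # not through re-randomized initialization
    ens.biases = update_bias(
        fit_pool, ens.cvs, K=schedule.K, increment=schedule.increment,
        n_replicas=R, seed=schedule.seed, window=schedule.window,
        previous=ens.biases, interval_index=ens.interval,
    )
    ens.bias_snapshots.append({
        "interval": ens.interval,
        "increment": schedule.increment,
        "models": {name: m.to_dict() for name, m in
                   _shared_models(ens.biases).items()},
    })
    return ens


@dataclass
class CampaignResult:
    """In-memory outputs of a campaign."""

    ensemble: EnsembleState
    schedule: ScheduleConfig

    @property
    def reference_positions(self) -> np.ndarray:
        """Reference-replica coordinates, shape (n_saved, n, d)."""
        parts = self.ensemble.reference_positions
        if not parts:
            return np.empty((0, 0, 0))
        return np.concatenate(parts, axis=0)

    @property
    def cv_history(self) -> pd.DataFrame:
        """Long-format table: step, interval, replica, one column per CV."""
        ens = self.ensemble
        rows = []
        for it, steps in enumerate(ens.cv_steps):
            R = next(iter(ens.cv_history.values()))[it].shape[1]
            for r in range(R):
                df = pd.DataFrame({"step": steps})
                df["interval"] = it
                df["replica"] = r + 1
                for name in ens.cv_history:
                    df[name] = ens.cv_history[name][it][:, r]
                rows.append(df)
        return (pd.concat(rows, ignore_index=True)
                .sort_values(["step", "replica"], ignore_index=True))

    @property
    def exchanges(self) -> pd.DataFrame:
        recs = self.ensemble.exchange_log
        return pd.DataFrame({
            "step": [e.step for e in recs],
            "replica_i": [e.pair[0] for e in recs],
            "replica_j": [e.pair[1] for e in recs],
            "delta": [e.delta for e in recs],
            "accepted": [e.accepted for e in recs],
        })

    def acceptance_by_pair(self) -> pd.DataFrame:
        ex = self.exchanges
        if ex.empty:
            return ex
        return (ex.groupby(["replica_i", "replica_j"])["accepted"]
                .mean().reset_index(name="acceptance"))

    @property
    def bias_snapshots(self) -> List[dict]:
        return self.ensemble.bias_snapshots


def run_campaign(
    spec: SystemSpec,
    cvs: Sequence[CVDefinition],
    schedule: ScheduleConfig,
    outdir: Optional[str] = None,
    restart: bool = False,
    record_trajectories: bool = False,
) -> CampaignResult:
    """Run a full adaptive H-REMD campaign.

    Fully reproducible from (spec, cvs, schedule): the schedule seed feeds
    one stream per replica plus one exchange stream.  With ``outdir`` set,
    outputs (cv_history.csv, exchanges.csv, bias_snapshots/, per-replica XYZ
    when ``record_trajectories``) and a per-interval checkpoint are written;
    ``restart=True`` resumes from the checkpoint after an interruption.
    """
    out = Path(outdir) if outdir is not None else None
    ens = None
    start_interval = 0
    if restart:
        if out is None:
            raise ValueError("restart requires an output directory")
        ckpt = out / "checkpoint.json"
        if ckpt.exists():
            ens = aio.load_checkpoint(ckpt, cvs)
            start_interval = ens.interval
            logger.info("restarting from interval %d", start_interval)
    if ens is None:
        ens = EnsembleState.initialize(spec, cvs, schedule)
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
        (out / "bias_snapshots").mkdir(exist_ok=True)

    traj_frames: List[np.ndarray] = []
    for _ in range(start_interval, schedule.n_intervals):
        run_interval(ens, spec, schedule)
        logger.info(
            "interval %d/%d done (step %d, %d exchange attempts logged)",
            ens.interval, schedule.n_intervals, ens.step, len(ens.exchange_log))
        if out is not None:
            aio.save_checkpoint(out / "checkpoint.json", ens)
            snap = ens.bias_snapshots[-1]
            with open(out / "bias_snapshots" / f"interval_{ens.interval:04d}.json",
                      "w") as fh:
                json.dump(snap, fh)
        if record_trajectories:
            traj_frames.append(ens.coords.copy())

    result = CampaignResult(ensemble=ens, schedule=schedule)
    if out is not None:
        result.cv_history.to_csv(out / "cv_history.csv", index=False)
        result.exchanges.to_csv(out / "exchanges.csv", index=False)
        refpos = result.reference_positions
        if len(refpos):
            aio.write_xyz(out / "replica_1.xyz", refpos,
                          comments=[f"step {i * schedule.reference_save_period}"
                                    for i in range(1, len(refpos) + 1)])
        if record_trajectories and traj_frames:
            stack = np.array(traj_frames)  # (n_intervals, R, n, d)
            for r in range(stack.shape[1]):
                aio.write_xyz(out / f"replica_{r + 1}_interval_end.xyz",
                              stack[:, r])
    return result
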