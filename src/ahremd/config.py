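"""Batch-file configuration: schema-validated YAML describing one campaign.

A run is fully specified by one file with ``system``, ``cv``, ``schedule``,
``bias`` and ``output`` blocks; unknown keys are rejected and defaults
(8 replicas, K=3, window 10, increment 4) are filled in and echoed to the
log.  Particle indices in CV groups are 0-based (unlike the 1-based residue
IDs of typical MD engines).
"""

from __future__ import annotations

from dataclasses import asdict
from pathlib import Path
from typing import Dict, List, Literal, Optional, Tuple

import numpy as np
import yaml
from pydantic import BaseModel, ConfigDict, Field, model_validator

from . import systems
from .cv import AtomGroup, CVDefinition
from .remd import ScheduleConfig

__all__ = ["RunConfig", "load_config", "dump_config", "build_system",
           "build_cvs", "build_schedule"]


class _Block(BaseModel):
    model_config = ConfigDict(extra="forbid")


class SystemBlock(_Block):
    fixture: Literal["double_well", "harmonic", "muller_brown", "bead_model"]
    # double well / bead-model inter-domain potential
    barrier_height: float = 6.0
    well_separation: float = 1.0
    # harmonic
    k: float = 1.0
    # muller_brown
    scale: float = 0.05
    # bead model
    n_domains: int = 2
    beads_per_domain: int = 4
    inter_domain: Tuple[float, float, float] = (4.0, 4.0, 8.0)
    seed: int = 0
    # thermodynamic state
    kT: float = 1.0
    friction: float = 1.0
    dt: float = 0.01


class CVPair(_Block):
    name: str
    group_a: str
    group_b: Optional[str] = None  # None -> distance to the origin


class CVBlock(_Block):
    groups: Dict[str, List[int]] = Field(default_factory=dict)
    pairs: List[CVPair] = Field(default_factory=list)


class ScheduleBlock(_Block):
    n_replicas: int = 8
    steps_per_interval: int = 10_000
    exchange_period: int = 80
    n_intervals: int = 20
    save_period: Optional[int] = None
    reference_save_period: Optional[int] = None
    seed: int = 0


class BiasBlock(_Block):
    increment: float = 4.0
    K: int = 3
    window: int = 10
    max_fit_replica: Optional[int] = None


class OutputBlock(_Block):
    directory: str = "campaign_out"
    record_trajectories: bool = False


class RunConfig(_Block):
    system: SystemBlock
    cv: CVBlock = Field(default_factory=CVBlock)
    schedule: ScheduleBlock = Field(default_factory=ScheduleBlock)
    bias: BiasBlock = Field(default_factory=BiasBlock)
    output: OutputBlock = Field(default_factory=OutputBlock)

    @model_validator(mode="after")
    def _check_cv_indices(self):
        spec = build_system(self)
        for name, idx in self.cv.groups.items():
            bad = [i for i in idx if not 0 <= i < spec.n_particles]
            if bad:
                raise ValueError(
                    f"cv.groups[{name!r}]: particle indices {bad} out of range "
                    f"(system has {spec.n_particles} particles, 0-based)"
                )
        known = set(self.cv.groups) | set(spec.groups)
        for pair in self.cv.pairs:
            for g in (pair.group_a, pair.group_b):
                if g is not None and g not in known:
                    raise ValueError(
                        f"cv.pairs[{pair.name!r}]: unknown group {g!r} "
                        f"(known: {sorted(known)})"
                    )
        return self


def build_system(cfg: RunConfig) -> systems.SystemSpec:
    s = cfg.system
    if s.fixture == "double_well":
        return systems.make_double_well(s.barrier_height, s.well_separation,
                                        kT=s.kT, friction=s.friction, dt=s.dt)
    if s.fixture == "harmonic":
        return systems.make_harmonic(k=s.k, kT=s.kT, friction=s.friction, dt=s.dt)
    if s.fixture == "muller_brown":
        return systems.make_muller_brown(scale=s.scale, kT=s.kT,
                                         friction=s.friction, dt=s.dt)
    return systems.make_domain_bead_model(
        n_domains=s.n_domains, beads_per_domain=s.beads_per_domain,
        inter_domain=s.inter_domain, seed=s.seed, kT=s.kT,
        friction=s.friction, dt=s.dt,
    )


def build_cvs(cfg: RunConfig, spec: systems.SystemSpec) -> List[CVDefinition]:
    """CVDefinitions from the config; defaults to sensible CVs per fixture
    when no pairs are given (|x| for 1-particle systems, consecutive domain
    COM distances for the bead model)."""
    groups = {name: np.asarray(idx, dtype=int) for name, idx in spec.groups.items()}
    groups.update({name: np.asarray(idx, dtype=int)
                   for name, idx in cfg.cv.groups.items()})

    def grp(name):
        idx = groups[name]
        return AtomGroup(name=name, indices=idx, masses=spec.masses[idx])

    pairs = cfg.cv.pairs
    if not pairs:
        if "domain_0" in groups:
            names = sorted([g for g in spec.groups if g.startswith("domain_")])
            pairs = [CVPair(name=f"CV_{i + 1}", group_a=names[i],
                            group_b=names[i + 1]) for i in range(len(names) - 1)]
        else:
            pairs = [CVPair(name="CV_1", group_a=next(iter(groups)), group_b=None)]
    return [CVDefinition(name=p.name, group_a=grp(p.group_a),
                         group_b=None if p.group_b is None else grp(p.group_b))
            for p in pairs]


def build_schedule(cfg: RunConfig) -> ScheduleConfig:
    sb = cfg.schedule
    return ScheduleConfig(
        n_replicas=sb.n_replicas, steps_per_interval=sb.steps_per_interval,
        exchange_period=sb.exchange_period, n_intervals=sb.n_intervals,
        window=cfg.bias.window, save_period=sb.save_period,
        reference_save_period=sb.reference_save_period, seed=sb.seed,
        K=cfg.bias.K, increment=cfg.bias.increment,
        max_fit_replica=cfg.bias.max_fit_replica,
    )


def load_config(path) -> RunConfig:
    """Load and validate a YAML batch file; schema violations are reported
    with their field paths."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected a mapping at top level")
    return RunConfig.model_validate(raw)


def dump_config(cfg: RunConfig, path=None) -> str:
    """Serialize a config back to YAML (round-trips through load_config)."""
    text = yaml.safe_dump(cfg.model_dump(mode="json"), sort_keys=False)
    if path is not None:
        Path(path).write_text(text)
    return text
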