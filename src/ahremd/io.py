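"""Plain-text I/O: XYZ trajectories, CSV tables, JSON checkpoints.

Toy-scale systems need nothing beyond the simplest standard formats: XYZ for
coordinates (one block per frame, the comment line carrying the step index),
CSV for CV/exchange tables (via pandas) and JSON for bias snapshots and
campaign checkpoints.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence

import numpy as np

__all__ = ["write_xyz", "read_xyz", "save_checkpoint", "load_checkpoint"]


def write_xyz(path, frames: np.ndarray, comments: Optional[Sequence[str]] = None,
              element: str = "C") -> None:
    """Write frames of shape (n_frames, n_particles, dim) as plain XYZ.

    Coordinates with dim < 3 are zero-padded to three columns.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[None]
    T, n, d = frames.shape
    if d < 3:
        pad = np.zeros((T, n, 3 - d))
        frames = np.concatenate([frames, pad], axis=-1)
    with open(path, "w") as fh:
        for t in range(T):
            fh.write(f"{n}\n")
            fh.write((comments[t] if comments is not None else f"frame {t}") + "\n")
            for i in range(n):
                x, y, z = frames[t, i]
                fh.write(f"{element} {x:.10g} {y:.10g} {z:.10g}\n")


def read_xyz(path) -> np.ndarray:
    """Read a plain XYZ file; returns coordinates (n_frames, n_particles, 3)."""
    frames: List[np.ndarray] = []
    with open(path) as fh:
        lines = fh.read().split("\n")
    i = 0
    while i < len(lines) and lines[i].strip():
        n = int(lines[i].strip())
        block = lines[i + 2:i + 2 + n]
        coords = np.array([[float(v) for v in ln.split()[1:4]] for ln in block])
        frames.append(coords)
        i += 2 + n
    return np.array(frames)


def _rng_state(g: np.random.Generator) -> dict:
    return g.bit_generator.state


def _rng_from_state(state: dict) -> np.random.Generator:
    g = np.random.default_rng()
    g.bit_generator.state = state
    return g


def save_checkpoint(path, ens) -> None:
    """Serialize an EnsembleState to JSON (restartable, bit-exact RNG state)."""
    payload = {
        "coords": ens.coords.tolist(),
        "velocities": ens.velocities.tolist(),
        "interval": ens.interval,
        "step": ens.step,
        "n_attempt_rounds": ens.n_attempt_rounds,
        "cv_history": {k: [a.tolist() for a in v] for k, v in ens.cv_history.items()},
        "cv_steps": [s.tolist() for s in ens.cv_steps],
        "exchange_log": [
            {"step": e.step, "pair": list(e.pair), "delta": e.delta,
             "accepted": e.accepted} for e in ens.exchange_log
        ],
        "reference_positions": [p.tolist() for p in ens.reference_positions],
        "bias_snapshots": ens.bias_snapshots,
        "biases": [b.to_dict() for b in ens.biases],
        "rng_states": [_rng_state(g) for g in ens.rngs],
        "exchange_rng_state": _rng_state(ens.exchange_rng),
    }
    tmp = Path(str(path) + ".tmp")
    with open(tmp, "w") as fh:
        json.dump(payload, fh)
    tmp.replace(path)


def load_checkpoint(path, cvs) -> "EnsembleState":
    from .bias import BiasState
    from .remd import EnsembleState, ExchangeRecord

    with open(path) as fh:
        d = json.load(fh)
    return EnsembleState(
        coords=np.array(d["coords"]),
        velocities=np.array(d["velocities"]),
        biases=[BiasState.from_dict(b) for b in d["biases"]],
        cvs=list(cvs),
        interval=d["interval"],
        step=d["step"],
        n_attempt_rounds=d["n_attempt_rounds"],
        cv_history={k: [np.array(a) for a in v] for k, v in d["cv_history"].items()},
        cv_steps=[np.array(s, dtype=int) for s in d["cv_steps"]],
        exchange_log=[
            ExchangeRecord(step=e["step"], pair=tuple(e["pair"]),
                           delta=e["delta"], accepted=e["accepted"])
            for e in d["exchange_log"]
        ],
        reference_positions=[np.array(p) for p in d["reference_positions"]],
        bias_snapshots=d["bias_snapshots"],
        rngs=[_rng_from_state(s) for s in d["rng_states"]],
        exchange_rng=_rng_from_state(d["exchange_rng_state"]),
    )
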