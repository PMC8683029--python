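"""Post-processing of reference-replica sampling.

Covers the analysis protocol applied to the unbiased reference replica:
free-energy profiles by Boltzmann inversion of CV histograms with block-
bootstrap error bands, per-particle RMSF about the average structure,
density-based conformational clustering (DBSCAN on a superposition-RMSD
metric with frame striding and sieving), and the interval-to-interval
bias-convergence diagnostic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import integrate, interpolate
from sklearn.cluster import DBSCAN

from .gmm import GMMModel, gmm_density

__all__ = [
    "integrated_autocorrelation_time",
    "FreeEnergyProfile",
    "free_energy_profile",
    "rmsf",
    "ClusterResult",
    "cluster_frames",
    "pairwise_rmsd",
    "bias_convergence",
    "boltzmann_cdf",
    "count_well_transitions",
]


def integrated_autocorrelation_time(x: np.ndarray, c: float = 5.0) -> float:
    """Integrated autocorrelation time (in sampling strides) of a scalar
    series, with Sokal's adaptive window (stop at the first W >= c * tau)."""
    x = np.asarray(x, dtype=float)
    n = len(x)
    if n < 2:
        return 1.0
    xc = x - x.mean()
    # FFT autocorrelation
    m = 1 << (2 * n - 1).bit_length()
    f = np.fft.rfft(xc, m)
    acf = np.fft.irfft(f * np.conjugate(f))[:n].real
    if acf[0] <= 0:
        return 1.0
    acf /= acf[0]
    tau = 1.0
    for w in range(1, n):
        tau = 1.0 + 2.0 * acf[1:w + 1].sum()
        if w >= c * tau:
            break
    return float(max(tau, 1.0))


@dataclass
class FreeEnergyProfile:
    """Binned free-energy profile, anchored so min(delta_g) = 0.

    Empty bins carry NaN in ``delta_g`` and ``error``.
    """

    bin_centers: np.ndarray
    delta_g: np.ndarray
    error: np.ndarray
    counts: np.ndarray
    kT: float = 1.0


def _profile_from_counts(counts: np.ndarray, kT: float) -> np.ndarray:
    with np.errstate(divide="ignore"):
        g = -kT * np.log(counts / counts.sum())
    g[counts == 0] = np.nan
    return g - np.nanmin(g)


def free_energy_profile(
    samples: np.ndarray,
    n_bins: int = 50,
    kT: float = 1.0,
    n_boot: int = 200,
    seed: int = 0,
    bin_range: Optional[tuple] = None,
) -> FreeEnergyProfile:
    """Boltzmann inversion of a CV histogram: dG(bin) = -kT ln p(bin), min 0.

    The error band is a block bootstrap: contiguous blocks of length equal to
    the estimated integrated autocorrelation time are resampled ``n_boot``
    times and the per-bin standard deviation of the re-anchored profiles is
    reported.
    """
    samples = np.asarray(samples, dtype=float).ravel()
    if len(samples) < 100:
        raise ValueError("need at least 100 samples for a profile")
    edges = np.histogram_bin_edges(samples, bins=n_bins, range=bin_range)
    centers = 0.5 * (edges[:-1] + edges[1:])
    counts, _ = np.histogram(samples, bins=edges)
    dg = _profile_from_counts(counts.astype(float), kT)

    tau = integrated_autocorrelation_time(samples)
    block = max(1, int(np.ceil(tau)))
    n_blocks = len(samples) // block
    rng = np.random.default_rng(seed)
    boots = np.full((n_boot, n_bins), np.nan)
    trimmed = samples[: n_blocks * block].reshape(n_blocks, block)
    for b in range(n_boot):
        pick = rng.integers(0, n_blocks, size=n_blocks)
        resampled = trimmed[pick].ravel()
        cts, _ = np.histogram(resampled, bins=edges)
        boots[b] = _profile_from_counts(cts.astype(float), kT)
    err = np.nanstd(boots, axis=0)
    err[counts == 0] = np.nan
    return FreeEnergyProfile(bin_centers=centers, delta_g=dg, error=err,
                             counts=counts, kT=kT)


def _kabsch(mobile: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Optimal proper rotation (d x d) aligning centered ``mobile`` onto
    centered ``ref`` in the least-squares sense."""
    h = mobile.T @ ref
    u, _, vt = np.linalg.svd(h)
    sign = np.sign(np.linalg.det(u @ vt))
    d = np.ones(h.shape[0])
    d[-1] = sign
    return u @ np.diag(d) @ vt


def _superpose_all(traj: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Center and rotate every frame onto the centered reference."""
    refc = ref - ref.mean(axis=0)
    out = np.empty_like(traj)
    for t in range(len(traj)):
        mob = traj[t] - traj[t].mean(axis=0)
        out[t] = mob @ _kabsch(mob, refc)
    return out


def rmsf(trajectory: np.ndarray, alignment: str = "none") -> np.ndarray:
    """Per-particle root-mean-square fluctuation about the average structure.

    ``alignment='rigid'`` first superposes every frame onto the (iteratively
    refined) average structure, removing global translation/rotation.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 3 or len(traj) < 2:
        raise ValueError("need a (n_frames, n_particles, dim) trajectory with >= 2 frames")
    if alignment not in ("none", "rigid"):
        raise ValueError("alignment must be 'none' or 'rigid'")
    if alignment == "rigid":
        ref = traj[0]
        for _ in range(3):
            traj = _superpose_all(traj, ref)
            ref = traj.mean(axis=0)
    mean = traj.mean(axis=0)
    disp2 = np.sum((traj - mean) ** 2, axis=-1)
    return np.sqrt(disp2.mean(axis=0))


def pairwise_rmsd(frames_a: np.ndarray, frames_b: Optional[np.ndarray] = None,
                  align: bool = True) -> np.ndarray:
    """Pairwise RMSD matrix between frame sets, with optimal rigid-body
    superposition per pair when ``align`` (the heavy-atom-RMSD analogue for
    bead models)."""
    A = np.asarray(frames_a, dtype=float)
    B = A if frames_b is None else np.asarray(frames_b, dtype=float)
    n = A.shape[1]
    Ac = A - A.mean(axis=1, keepdims=True)
    Bc = B - B.mean(axis=1, keepdims=True)
    out = np.empty((len(A), len(B)))
    for i in range(len(A)):
        for j in range(len(B)):
            if frames_b is None and j < i:
                out[i, j] = out[j, i]
                continue
            if frames_b is None and j == i:
                out[i, j] = 0.0
                continue
            b = Bc[j]
            if align:
                b = b @ _kabsch(b, Ac[i])
            out[i, j] = np.sqrt(np.sum((Ac[i] - b) ** 2) / n)
    return out


@dataclass
class ClusterResult:
    """DBSCAN clustering of trajectory frames.

    ``labels`` covers the strided (analyzed) frames: cluster id >= 0 or -1
    for noise.  ``populations`` are fractions of analyzed frames per cluster
    (noise excluded, so they sum to <= 1); ``representatives`` maps cluster
    id to the medoid's index into the analyzed-frame list, and
    ``analyzed_indices`` maps back into the original trajectory.
    """

    labels: np.ndarray
    populations: Dict[int, float]
    representatives: Dict[int, int]
    analyzed_indices: np.ndarray


def cluster_frames(
    trajectory: np.ndarray,
    eps: float = 1.25,
    min_samples: int = 4,
    frame_stride: int = 5,
    sieve: int = 10,
    seed: int = 0,
    align: bool = True,
) -> ClusterResult:
    """Density-based conformational clustering with striding and sieving.

    Every ``frame_stride``-th frame is analyzed (memory control).  Of those,
    a 1-in-``sieve`` subset (random phase per ``seed``) is clustered with
    DBSCAN using pairwise superposition RMSD as the metric; the remaining
    analyzed frames are then assigned to the cluster of their nearest core
    point within ``eps``, or to noise.  Representatives are cluster medoids.
    Fewer than ``min_samples`` analyzed frames yield an all-noise result.
    """
    traj = np.asarray(trajectory, dtype=float)
    if traj.ndim != 3:
        raise ValueError("trajectory must have shape (n_frames, n_particles, dim)")
    analyzed_idx = np.arange(0, len(traj), frame_stride)
    frames = traj[analyzed_idx]
    nA = len(frames)
    labels = np.full(nA, -1, dtype=int)
    if nA == 0:
        return ClusterResult(labels, {}, {}, analyzed_idx)

    rng = np.random.default_rng(seed)
    phase = int(rng.integers(sieve)) if sieve > 1 else 0
    sub = np.arange(phase % max(sieve, 1), nA, max(sieve, 1))
    if len(sub) == 0:
        sub = np.array([0])
    dmat = pairwise_rmsd(frames[sub], align=align)
    if dmat.max() == 0.0 and len(sub) >= min_samples:
        sub_labels = np.zeros(len(sub), dtype=int)  # degenerate metric
        core_mask = np.ones(len(sub), dtype=bool)
    else:
        db = DBSCAN(eps=eps, min_samples=min_samples, metric="precomputed").fit(dmat)
        sub_labels = db.labels_
        core_mask = np.zeros(len(sub), dtype=bool)
        core_mask[db.core_sample_indices_] = True
    labels[sub] = sub_labels

    # add the sieved-out frames to the formed clusters
    core_idx = sub[core_mask]
    rest = np.setdiff1d(np.arange(nA), sub)
    if len(core_idx) and len(rest):
        d_rest = pairwise_rmsd(frames[rest], frames[core_idx], align=align)
        nearest = np.argmin(d_rest, axis=1)
        within = d_rest[np.arange(len(rest)), nearest] <= eps
        core_labels = labels[core_idx]
        labels[rest[within]] = core_labels[nearest[within]]

    ids = sorted(set(labels[labels >= 0]))
    populations = {int(k): float((labels == k).sum()) / nA for k in ids}
    representatives = {}
    for k in ids:
        members = np.where(labels == k)[0]
        dm = pairwise_rmsd(frames[members], align=align)
        representatives[int(k)] = int(members[np.argmin(dm.sum(axis=1))])
    return ClusterResult(labels=labels, populations=populations,
                         representatives=representatives,
                         analyzed_indices=analyzed_idx)


def bias_convergence(snapshots: Sequence[dict], cv: str,
                     grid: np.ndarray) -> dict:
    """Interval-to-interval drift of the bias curve for one CV.

    Evaluates each snapshot's bias at replica-2 scale (increment * p(x)) on
    ``grid`` and reports the RMS difference between consecutive intervals,
    plus the overall curve maximum and an early-vs-late drift summary.
    Missing models for the CV are flagged as gaps.
    """
    grid = np.asarray(grid, dtype=float)
    if len(snapshots) < 2:
        raise ValueError("need at least two interval snapshots")
    curves, intervals, gaps = [], [], []
    for snap in snapshots:
        models = snap.get("models", {})
        if cv not in models:
            gaps.append(snap.get("interval"))
            continue
        model = GMMModel.from_dict(models[cv])
        curves.append(snap.get("increment", 1.0) * gmm_density(model, grid))
        intervals.append(snap.get("interval"))
    curves = np.array(curves)
    drift = np.sqrt(np.mean(np.diff(curves, axis=0) ** 2, axis=1))
    bias_max = float(curves.max()) if len(curves) else np.nan
    n = len(drift)
    early = float(np.median(drift[: max(n // 2, 1)]))
    late = float(np.median(drift[n - max(n // 4, 1):]))
    return {
        "intervals": np.array(intervals[1:]),
        "drift": drift,
        "bias_max": bias_max,
        "early_median": early,
        "late_median": late,
        "gaps": gaps,
    }


def boltzmann_cdf(energy_fn, kT: float, xmin: float, xmax: float,
                  n: int = 4001):
    """Analytic (quadrature) Boltzmann CDF of a 1D potential, as a callable
    suitable for a Kolmogorov-Smirnov test."""
    x = np.linspace(xmin, xmax, n)
    w = np.exp(-(energy_fn(x) - energy_fn(x).min()) / kT)
    cdf = integrate.cumulative_trapezoid(w, x, initial=0.0)
    cdf /= cdf[-1]
    return interpolate.interp1d(x, cdf, bounds_error=False, fill_value=(0.0, 1.0))


def count_well_transitions(x: np.ndarray, well_position: float,
                           core_fraction: float = 0.5) -> int:
    """Count transitions between the two wells of a symmetric double well.

    Uses hysteresis: a transition is registered only when the trajectory
    passes from one core region (|x| > core_fraction * well_position, one
    sign) to the other, so barrier recrossings are not double-counted.
    """
    x = np.asarray(x, dtype=float).ravel()
    thr = core_fraction * well_position
    state = 0
    n = 0
    for xi in x:
        if xi > thr:
            if state == -1:
                n += 1
            state = 1
        elif xi < -thr:
            if state == 1:
                n += 1
            state = -1
    return n
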