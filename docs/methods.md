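# Methods

## Model and sampler

`ahremd` samples a system of point particles with a BAOAB-splitting Langevin
integrator (half-kick, half-drift, exact Ornstein–Uhlenbeck velocity
refresh, half-drift, half-kick).  The O-step uses the exact damping factor
`a = exp(−γ dt)` and noise amplitude `√(kT(1 − a²)/m)`, so the scheme is
stable at moderate time steps and its configurational sampling error is
O(dt²).  Reduced units are used throughout: masses, lengths and kT are O(1),
and the bias increment Δ is expressed in the same energy units (Δ = 4 means
four thermal energies for a kT = 1 system, preserving the ratio of bias
scale to thermal energy that a production setup with Δ = 4 kcal/mol at
~300 K would have at its own CV scale).

The H-REMD ensemble holds `R` structurally identical replicas at one
temperature.  Replica `r` carries the bias `B_r = Σ_CV (r−1)·Δ·p_CV(x_CV)`
with a shared per-CV Gaussian-mixture density `p_CV`.  The campaign proceeds
in intervals: propagate every replica `steps_per_interval` steps with its
bias force (chain rule through the CV gradient), attempt configuration swaps
between adjacent replicas every `exchange_period` steps with alternating
even/odd pairing, then refit `p_CV` on the CV samples of all replicas pooled
over the last `window` intervals.  The first interval is unbiased — it
seeds the density estimate.  Defaults preserve the cadence ratios of a
production protocol as step ratios: exchanges every 80 steps, 10,000-step
intervals, window 10, save cadence = exchange cadence, 8 replicas, Δ = 4,
K = 3.

Because all replicas share temperature and physical Hamiltonian, the
Metropolis exponent for swapping configurations `x_i ↔ x_j` is

    Δ_ij = [B_i(ξ(x_j)) + B_j(ξ(x_i))] − [B_i(ξ(x_i)) + B_j(ξ(x_j))],

the unbiased energies cancel.  With the shared mixture models this further
reduces to `(pref_i − pref_j)(P(x_j) − P(x_i))` with `pref_r = (r−1)Δ` and
`P = Σ_CV p_CV`, which the inner loop exploits.  Configurations (coordinates
and velocities) move between bias slots; replica 1 is the fixed zero-bias
slot, so its trajectory samples the unbiased Boltzmann distribution exactly
whenever the bias is held fixed — under adaptation this is exact only in the
limit of a converged bias, which the convergence diagnostic monitors.

## Collective variables

A CV is the distance between the mass-weighted centers of two disjoint
particle groups; its analytic gradient places `±(m_i/M_group)·(unit vector)`
on the group members and zero elsewhere.  For one-particle 1D systems the
second group is replaced by a fixed reference point at the origin, making the
CV |x|; this stays within the COM-distance family and keeps the biased
dynamics symmetric in x.  Group indices are 0-based.  Separations below
1e−8 are declared singular: the CV value 0 is legal but the gradient
direction is undefined, so that CV's bias force is dropped for the step.

## Mixture fitting

`fit_gmm` is a univariate EM with: seeded initialization (k-means-style
Lloyd assignment started from K samples drawn by the seeded generator),
log-sum-exp E-step, a width floor of 1e−3 of the sample range, relative
log-likelihood tolerance 1e−6 and at most 500 iterations.  The σ parameters
are standard deviations.  The per-iteration log-likelihood path is kept on
the model — EM guarantees it is non-decreasing, which the tests assert.  At
least `10·K` samples are required; all-equal samples yield a single
effective component with a floored width.  Within a campaign the refit uses
a fixed seed, so consecutive fits differ only through the sliding data
window, not through re-randomized initialization.  A hand-written kernel
(numba-compiled when available) makes the ~100-iteration fits on 10,000
pooled samples take tens of milliseconds; a vectorized numpy fallback
implements the same arithmetic.

Dimensional note: `p(x)` has units 1/CV-length, so the effective bias height
depends on the CV scale; for the 1D wells used here the peak bias on replica
8 reaches ~(R−1)·Δ·p_max ≈ 70–80 kT, which strongly flattens (indeed
inverts) the landscape for the top replicas while the reference stays
unbiased.

## Analyses

- **Free-energy profiles**: ΔG(bin) = −kT ln p̂(bin), min-anchored at zero;
  empty bins are masked (NaN).  Errors are block-bootstrap bands: block
  length = ⌈integrated autocorrelation time⌉ of the sample series (Sokal
  window, c = 5), 200 resamples, per-bin standard deviation of re-anchored
  profiles.
- **RMSF**: per particle, RMS displacement from the time-average structure;
  `rigid` mode first superposes every frame onto the iteratively refined
  average (Kabsch), making the result invariant under global rotations.
- **Clustering**: pairwise best-superposition RMSD is the metric (the
  bead-model analogue of heavy-atom RMSD).  Every 5th frame is analyzed; a
  1-in-10 "sieve" subset (random phase per seed) is clustered with DBSCAN
  (eps 1.25, min_samples 4); remaining frames join the cluster of their
  nearest core point within eps, else noise.  Representatives are medoids;
  populations are fractions of analyzed frames with noise excluded (they sum
  to ≤ 1).
- **Bias convergence**: the bias curve at replica-2 scale (Δ·p) is evaluated
  on a grid per interval; drift is the RMS difference between consecutive
  curves (grid-normalized L2, so the number is grid-resolution-free).  The
  summary statistic is the *median* drift over the final quarter of the
  campaign as a fraction of the maximum bias on the grid — a median because
  single-interval refits occasionally jump (component reshuffling) even
  after the estimate has stabilized.

## Model systems

The double well `U(x) = h((x/a)² − 1)²` (minima ±a, barrier h) and harmonic
well are the workhorses; a scaled 2D Mueller–Brown surface is included for
experimentation.  The domain bead model emulates multidomain lobe motion:
each domain is a near-rigid cluster (all intra-domain pairs bonded
harmonically at their jittered-lattice rest lengths, k = 100), and
consecutive domain COM distances feel a double well with minima at chosen
"closed" and "open" separations.  Construction is deterministic per seed and
rejects initial placements with bead pairs closer than a threshold.  What
these systems do *not* emulate: solvent friction anisotropy, rugged
all-atom landscapes, CV cross-coupling through shared atoms — so passing
tests demonstrate correctness of the sampler and protocol, not production
force-field behavior.

## Validation studies and problem sizes

The benchmark suite (also driven by `scripts/acceptance.py`) uses:

- **Boltzmann correctness**: 8 replicas on the h = 6 kT double well,
  dt = 0.02, friction 1, 3000 intervals of 10,000 steps (30M steps per
  replica), reference positions saved every 40 steps.  After a 10% burn-in
  the series is subsampled at its integrated autocorrelation time
  (~1.5–3k steps — set jointly by ladder round-trip time and the reference's
  own barrier crossings) giving ≥10,000 approximately independent samples
  for a one-sample KS test against the quadrature Boltzmann CDF.  dt = 0.02
  keeps the discretization bias (O((ωdt)²) ≈ 0.2%) far below the KS
  resolution at this n.
- **Acceleration**: h = 8 kT, 10 seeds, 150,000 steps per trajectory;
  inter-well transitions are counted with a hysteresis threshold at
  |x| > 0.5a.  Plain Langevin shows ~0–1 transitions per run at this
  budget; the H-REMD reference typically shows hundreds.
- **Mixture recovery**: φ = (0.5, 0.3, 0.2), μ = (−2, 0, 3),
  σ = (0.5, 0.4, 0.6), 5000 samples, 20 seeds, nearest-mean matching.
- **Force consistency**: central differences (h = 1e−6) of the bias energy
  vs analytic bias forces on 100 random bead-model states, two COM CVs.
- **Exchange statistics**: identical-bias pairs must always accept
  (exp(0) = 1 ≥ any uniform draw); a pair engineered to have exponent
  exactly 1 accepts at e⁻¹ within 3σ over 1e5 draws.
- **Null bias**: Δ = 0 on an h = 2 kT double well, 1M steps, two-sample KS
  of the reference slot against an independent plain run.
- **Free-energy recovery**: harmonic well, 2M steps, profile within two
  bootstrap bands of x²/2 on |x| ≤ 2.
- **Clustering**: three planted conformer families of 200 frames each whose
  reference structures differ in size (superposition cannot align them), so
  with eps/min/stride/sieve = 1.25/4/5/10 each family keeps ≥4 sieved
  frames and is recovered exactly with zero noise.  Note that with much
  shorter trajectories (e.g. 50 frames per family) the 1-in-10 sieve of the
  1-in-5 strided set leaves fewer than min_samples frames per family and
  everything is correctly classified as noise — the protocol needs
  ≥ stride·sieve·min_samples frames per state it is to resolve.

## Design choices and limitations

- Neighbor-only swaps with alternating parity (standard, ergodic); whether a
  production implementation attempts all pairs is immaterial for detailed
  balance.
- Pooled fit samples are used unweighted, including biased replicas; no
  reweighting is applied before the fit.  A `max_fit_replica` option allows
  sensitivity checks that exclude the high replicas.
- The bias switches abruptly at interval boundaries; exchange bookkeeping
  always uses the current interval's bias.
- Per-replica RNG streams plus one exchange stream are spawned from the
  schedule seed; campaigns, including the exchange log, are bitwise
  reproducible and restartable from JSON checkpoints.
- The adaptive reference replica is only asymptotically unbiased (see
  above); analyses should discard the pre-convergence portion, and the
  drift diagnostic indicates when that is.
- No multivariate mixtures (each CV is biased independently), no
  well-tempered deposition schemes, no explicit solvent or periodic
  boundaries, no temperature ladders.
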