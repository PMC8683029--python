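# ahremd — adaptive Hamiltonian replica exchange with Gaussian-mixture bias potentials

`ahremd` implements an adaptive Hamiltonian replica-exchange (H-REMD) sampler
for systems with slow, large-scale conformational motion, together with the
analysis protocol used to interpret such simulations.  It is aimed at people
who study enhanced-sampling methods: every ingredient of the sampler —
collective variables, density estimation, bias construction, exchange
bookkeeping — is exposed as a small, testable library, and desk-scale model
systems (analytic wells and a coarse-grained domain bead model) make the whole
pipeline runnable on a laptop in minutes.

## The method

A set of `R` replicas (default 8) runs at one temperature and shares one
physical Hamiltonian.  Replica `r` additionally feels a bias potential on a
set of collective variables (CVs) — center-of-mass distances between particle
groups:

```
B_r(x) = Σ_CV (r − 1) · Δ · p_CV(x_CV),        Δ = 4 energy units,
p(x)   = Σ_{k=1..K} φ_k N(x | μ_k, σ_k),       K = 3,  Σ φ_k = 1,
```

where `p` is a Gaussian-mixture density fitted by expectation–maximization to
the CV samples of *all* replicas pooled over a sliding window of the last 10
intervals (an *interval* is one cycle of sampling → CV analysis → bias
update; the first interval runs unbiased).  Because `p` peaks where sampling
has concentrated, the bias destabilizes the currently sampled region and
pushes the high replicas into new territory; configuration swaps between
adjacent replicas, accepted with the Metropolis probability
`min(1, exp(−Δ_ij/kT))` where the exponent reduces to bias-energy
differences, feed those configurations back to the unbiased *reference
replica* (replica 1).  Only the reference replica is analyzed: its samples
follow the plain Boltzmann distribution, so no reweighting is needed.

Analyses provided: free-energy profiles by Boltzmann inversion of CV
histograms with autocorrelation-aware block-bootstrap error bands, RMSF about
the (optionally superposed) average structure, DBSCAN conformational
clustering on a superposition-RMSD metric with frame striding and sieving,
and a bias-convergence diagnostic (interval-to-interval drift of the bias
curve).

## Worked example

Run an adaptive H-REMD campaign on a 1D double well with a 6 kT barrier
(the shipped batch file uses 8 replicas, Δ = 4 kT, K = 3, window 10):

```bash
ahremd run -c examples/double_well.yaml --seed 1
ahremd analyze --cv-history campaign_out/cv_history.csv --out analysis_out
ahremd convergence --snapshots campaign_out/bias_snapshots --cv CV_1
```

The `run` log ends with the per-pair exchange acceptance, e.g.

```
exchange acceptance by pair:
 replica_i  replica_j  acceptance
         1          2       0.624
         2          3       0.744
         3          4       0.792
         4          5       0.848
         5          6       0.784
         6          7       0.800
         7          8       0.800
```

— healthy neighbor acceptance (here 0.6–0.85) means configurations migrate
freely across the ladder.  `analyze` writes `profiles.csv`; on the double
well the reference-replica profile reproduces the quartic `h((x/a)² − 1)²`
with its two minima and the 6 kT barrier within the shaded bootstrap band,
anchored at min ΔG = 0.  `convergence` prints

```
bias max 12.62; early median drift 0.7111; late median drift 0.4097; written to convergence.csv
```

— the drift between consecutive bias curves settles to a few percent of the
bias maximum once the density estimate has converged (the analogue of a
stationary bias late in a production campaign).

The same machinery runs on multi-domain bead models
(`fixture: bead_model`), whose domains toggle between closed and open
COM-distance states through a double-well coupling — a desk-scale stand-in
for lobe motions of a multidomain protein.

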