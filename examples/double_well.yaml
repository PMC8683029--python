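# Minimal batch file: adaptive H-REMD on the 1D double well (barrier 6 kT).
# Defaults fill in 8 replicas, K=3 mixture components, window 10 intervals,
# increment 4 kT; CV_1 defaults to the particle's COM distance to the origin.
system:
  fixture: double_well
  barrier_height: 6.0
  well_separation: 1.0
schedule:
  steps_per_interval: 2000
  exchange_period: 80
  n_intervals: 10
  seed: 1
output:
  directory: campaign_out
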