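# End-to-end demo run: simulate a small population, build the 7-year
# cohort, apply all 15 algorithms to all three sites, estimate overall and
# state-stratified incidences and compare them to the simulated registry
# benchmark.  Invoke as:  claimsinc run --config examples/run.yaml
out_dir: scratch/demo_run
simulation:
  n_persons: 10000
  seed: 20130101
cohort:
  reference_date: "2013-01-01"
  required_years: 7
  max_gap_days: 28
algorithms: all
sites: [breast, prostate, colorectal]
strata: [overall, sex, state]
standard: esp1976
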