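# Worked relaxation scenario: the stabilizing gain calibrates to exactly 0.5
# from the pre-transition schedule (maternal-only deficit 1 - 0.4/0.8), the
# post-transition schedule carries unit relative risks (loss 0), so the
# allele-pool frequency steps 10% -> 15% -> 22.5% ... after the transition.
arch:
  n_loci: 1000
  effect_per_allele: 0.1
  baseline_bmi: 25.0
  reference_freq: 0.10
  env_sd: 3.0
  obesity_threshold: 30.0
pre_schedule:
  lmdr: 0.2
  neonatal_rate: 0.0
  rr_maternal: 3.0
  rr_perinatal: 1.0
  fertility: 6.0
post_schedule:
  lmdr: 0.0001
  neonatal_rate: 0.003
  rr_maternal: 1.0
  rr_perinatal: 1.0
  fertility: 2.0
transition_generation: 2
transition_year: 1940
n_generations: 8
generation_years: 25
mode: deterministic
initial_freq: 0.10
seed: 1
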