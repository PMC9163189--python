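# Reduced-scale synthetic CSP run: oracle dataset -> fit -> random
# packing in two space groups -> staged minimization -> ranking.
monomer: diatomic
n_points: 500
noise_sigma: 0.0
form: extended
seed: 1
outdir: csp_run
generation:
  mode: random
  space_groups: [P1, P-1]
  per_group_quota_step1: 40
  per_group_quota_step2: 20
  seed: 1
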