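# Small end-to-end demonstration: synthetic norms, 12 simulated subjects,
# 1000 permutations at FWE p < 0.001, leave-one-out clustering.
seed: 1
out_dir: demo_out
n_subjects: 12
n_perm: 1000
fwe_alpha: 0.001
stat: r2
adaptation_alpha: 0.001
k_range: [2, 6]
consensus_threshold: 0.75
run_behavioral: true
rt:
  n_subjects: 12
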