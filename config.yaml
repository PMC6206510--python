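# Example pipeline configuration for the demo study.
out_dir: results/run
seed: 7
depth: 5
maf_threshold: 0.05
qc_z_threshold: 2.0
pa_iterations: 50
pa_subsample: 500
pa_max_rank: 30
weights_mode: unweighted
alpha: 0.05
subgroup: all
simulation:
  n_subjects: [300, 200, 400]
  n_landmarks: 96
  seed: 7
  snps:
    - {snp_id: rs1000, maf: 0.10}
    - {snp_id: rs1001, maf: 0.13}
    - {snp_id: rs1002, maf: 0.16}
    - {snp_id: rs1003, maf: 0.19}
    - {snp_id: rs1004, maf: 0.22}
    - {snp_id: rs1005, maf: 0.25}
    - {snp_id: rs1006, maf: 0.28}
    - {snp_id: rs_rare1, maf: 0.02}
    - {snp_id: rs_rare2, maf: 0.03}
    - {snp_id: rs_planted, maf: 0.20, beta: 1.5, target_module: mandible}
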