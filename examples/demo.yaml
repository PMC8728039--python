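# End-to-end demo: a scaled-down breeding program (about 500 samples x
# 2,000 markers) simulated, QC'd, ordinated, and evaluated with reduced
# Gibbs chains.  Run:  tetragp run-all --config examples/demo.yaml
output_dir: scratch/demo_run
seed: 42
trait: TW
max_missing: 0.10
min_maf: 0.05
pcoa_axes: 2
cv_folds: 5
cv_reps: 5
cross_family_pair: [T1-C, T1-D]
train_generations: [T2, T3-7]
test_generations: [T1-A, T1-B, T1-C, T1-D, T1-E]
include_parents: true
sim:
  n_markers: 2000
  family_sizes: [40, 40, 100, 110, 60]
  generation_sizes: [105, 45]
  alpha_dr: 0.05
  missing_rate: 0.02
  seed: 42
brr:
  n_iter: 1500
  burn_in: 500
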