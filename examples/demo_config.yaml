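# Demo cohort: 20 genes, 3 x 4 samples, planted retention / expression /
# methylation / peak structure. Run with:
#   intronret run examples/demo_config.yaml
# or examples/run_pipeline.py
seed: 7
output_dir: out/demo
simulate:
  n_genes: 20
  introns_per_gene: 2
  n_affected: 10
  n_inverse: 5
  delta_r: 0.25
  n_samples:
    diagnosis: 4
    remission: 4
    control: 4
thresholds:
  t_ratio: 0.1
  t_depth: 3
  t_total: 10
dmr:
  min_cpg: 5
  min_delta: 0.1
  alpha: 0.05
  max_gap: 250
comparison: [diagnosis, control]
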