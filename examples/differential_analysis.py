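"""Differential expression, intron retention, and exon usage between
diagnosis and control samples of a simulated cohort.

The same two-group negative-binomial Wald test underlies all three analyses;
what changes is the exposure term (size factors, total splicing evidence, or
host-gene counts).
"""

import pandas as pd

from intronret import CohortConfig, build_truth, measure_introns, simulate_reads
from intronret.pipeline import exon_count_matrix, feature_count_matrix, ir_count_matrices
from intronret.stats import differential_exon_usage, differential_ir, nb_wald_test

cfg = CohortConfig(
    n_genes=12, n_affected=6, n_inverse=3,
    n_samples={"diagnosis": 5, "remission": 0, "control": 5},
)
truth = build_truth(cfg, seed=2)
samples = list(truth.sample_sheet["sample"])
reads = {s: simulate_reads(truth, s) for s in samples}
tables = {s: measure_introns(reads[s], truth.introns, sample=s) for s in samples}

groups = pd.Series(
    truth.sample_sheet.set_index("sample")["condition"], index=samples
)
gene_mat = feature_count_matrix(reads, truth.annotation)
intronic, junction = ir_count_matrices(tables, truth.introns)
exon_mat, exon_genes = exon_count_matrix(reads, truth.annotation)

genes = nb_wald_test(gene_mat, groups)
introns = differential_ir(intronic, junction, groups)
exons = differential_exon_usage(exon_mat, gene_mat, exon_genes, groups)

print("Top differential genes (log2 FC diagnosis over control):")
print(genes.nsmallest(4, "q_value")[["feature_id", "log2_fc", "q_value"]]
      .to_string(index=False, float_format="%.3g"))
print("\nTop differentially retained introns (delta IR = diagnosis - control):")
print(introns.nsmallest(4, "q_value")[["feature_id", "delta_ir", "q_value"]]
      .to_string(index=False, float_format="%.3g"))
print(f"\nExon usage calls at q<0.05: {(exons['q_value'] < 0.05).sum()}")
print()
print("Three genes were planted 4-fold down at diagnosis (log2 FC near -2)")
print("and six introns with retention raised by 0.25 (delta IR near +0.25).")
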