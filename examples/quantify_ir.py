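"""Quantify intron retention from simulated spliced alignments.

Builds a one-condition cohort with a known retention fraction, measures
each intron's IR ratio (intronic depth / (intronic depth + junction reads)),
and compares the estimates with the planted truth.
"""

import pandas as pd

from intronret import CohortConfig, build_truth, measure_introns, simulate_reads

cfg = CohortConfig(
    n_samples={"diagnosis": 1, "remission": 0, "control": 0},
    n_genes=6, introns_per_gene=1, n_affected=3, n_inverse=0,
    base_retention=0.05, delta_r=0.25,
    mu_range=(2000, 2000),
)
truth = build_truth(cfg, seed=1)
reads = simulate_reads(truth, "dia_01")
table = measure_introns(reads, truth.introns, sample="dia_01")
table["planted_r"] = table["intron_id"].map(truth.retention["diagnosis"])

print(table[["intron_id", "junction_count", "intronic_depth", "ir_ratio", "planted_r"]]
      .to_string(index=False, float_format="%.3f"))
print()
print("Each row is one intron: the IR ratio estimates the fraction of the")
print("gene's transcripts retaining that intron and should match planted_r")
print("up to counting noise (three introns were planted at r = 0.30).")
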