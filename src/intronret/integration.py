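"""Cross-omic integration screens.

TPM expression units, the ΔIR × expression inverse-relationship screen
(introns whose retention change opposes their host gene's expression
change), the per-gene Spearman correlation of expression with per-sample IR
event frequencies, and length/GC comparisons of retained vs non-retained
introns.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .annotation import IntronUnit
from .irquant import SampleIRSummary
from .stats import mann_whitney_u


def compute_tpm(
    counts: pd.DataFrame | pd.Series, effective_lengths: pd.Series
) -> pd.DataFrame | pd.Series:
    """Transcripts-per-million from counts and effective lengths.

    TPM_g = 1e6 * (count_g / length_g) / sum_h (count_h / length_h); each
    sample column sums to 1e6.
    """
    lengths = pd.Series(effective_lengths, dtype=float)
    if (lengths <= 0).any():
        raise ValueError("effective lengths must be positive")
    if isinstance(counts, pd.Series):
        rate = counts / lengths.reindex(counts.index)
        return 1e6 * rate / rate.sum()
    rate = counts.div(lengths.reindex(counts.index), axis=0)
    return 1e6 * rate / rate.sum(axis=0)


def inverse_relation_screen(
    diff_ir: pd.DataFrame,
    diff_expr: pd.DataFrame,
    intron_to_gene: Mapping[str, str] | pd.Series | None = None,
    ir_thresh: float = 0.1,
    fc_thresh: float = 1.0,
) -> pd.DataFrame:
    """Introns whose retention change opposes host-gene expression change.

    A hit requires |delta_ir| >= ir_thresh, |log2_fc| >= fc_thresh (host
    gene), and opposite signs. Both directions are reported
    (``ir_up_expr_down`` / ``ir_down_expr_up``). Introns whose host gene has
    no expression record are skipped (count logged).
    """
    ir = diff_ir.copy()
    if intron_to_gene is not None:
        mapping = pd.Series(intron_to_gene)
        ir["gene_id"] = ir["feature_id"].map(mapping)
    if "gene_id" not in ir:
        raise ValueError("diff_ir needs a gene_id column or an intron_to_gene mapping")
    expr = diff_expr.set_index("feature_id")["log2_fc"]
    ir["log2_fc_gene"] = ir["gene_id"].map(expr)
    skipped = int(ir["log2_fc_gene"].isna().sum())
    if skipped:
        import logging

        logging.getLogger(__name__).info(
            "%d introns without host-gene expression record skipped", skipped
        )
    ir = ir.dropna(subset=["log2_fc_gene", "delta_ir"])
    hit = (
        (ir["delta_ir"].abs() >= ir_thresh)
        & (ir["log2_fc_gene"].abs() >= fc_thresh)
        & (np.sign(ir["delta_ir"]) != np.sign(ir["log2_fc_gene"]))
        & (np.sign(ir["delta_ir"]) != 0)
    )
    hits = ir.loc[hit, ["feature_id", "gene_id", "delta_ir", "log2_fc_gene"]].copy()
    hits = hits.rename(columns={"feature_id": "intron_id", "log2_fc_gene": "log2_fc"})
    hits["direction"] = np.where(
        hits["delta_ir"] > 0, "ir_up_expr_down", "ir_down_expr_up"
    )
    return hits.reset_index(drop=True)


def ir_frequency_correlation(
    tpm: pd.DataFrame,
    summaries: Sequence[SampleIRSummary] | pd.DataFrame,
) -> pd.DataFrame:
    """Per-gene Spearman correlation of expression with IR event frequency.

    For each gene, rho between its TPM vector and the per-sample IR event
    counts across samples; two-sided p (exact null for n <= 9, t
    approximation otherwise, as provided by scipy). Output ranked by |rho|;
    constant expression vectors are flagged with rho = NaN.
    """
    if not isinstance(summaries, pd.DataFrame):
        summaries = pd.DataFrame([s.__dict__ for s in summaries])
    freq = summaries.set_index("sample")["n_ir_events"]
    common = [s for s in tpm.columns if s in freq.index]
    if len(common) < 5:
        raise ValueError("need at least 5 samples with both TPM and IR frequency")
    x = freq.reindex(common).to_numpy(dtype=float)
    rows = []
    for gene_id, row in tpm[common].iterrows():
        y = row.to_numpy(dtype=float)
        if np.all(y == y[0]) or np.all(x == x[0]):
            rows.append(
                {"gene_id": gene_id, "rho": np.nan, "p_value": np.nan,
                 "n": len(common), "flagged": True}
            )
            continue
        rho, p = sps.spearmanr(y, x)
        rows.append(
            {"gene_id": gene_id, "rho": float(rho), "p_value": float(p),
             "n": len(common), "flagged": False}
        )
    out = pd.DataFrame(rows)
    out["abs_rho"] = out["rho"].abs()
    out = out.sort_values("abs_rho", ascending=False, kind="stable").drop(columns="abs_rho")
    return out.reset_index(drop=True)


def intron_feature_compare(
    retained: Sequence[IntronUnit], non_retained: Sequence[IntronUnit]
) -> dict[str, dict]:
    """Length and GC-content comparison of retained vs non-retained introns.

    Returns per attribute the group medians, a two-sided Mann–Whitney p, and
    the direction of the retained group relative to the non-retained group.
    """
    if not retained or not non_retained:
        raise ValueError("both intron groups must be non-empty")
    out = {}
    for name, getter in (
        ("length", lambda iv: iv.length),
        ("gc", lambda iv: iv.gc_fraction),
    ):
        a = np.array([getter(iv) for iv in retained], dtype=float)
        b = np.array([getter(iv) for iv in non_retained], dtype=float)
        _, p = mann_whitney_u(a, b)
        med_a, med_b = float(np.median(a)), float(np.median(b))
        direction = (
            "retained_higher" if med_a > med_b
            else "retained_lower" if med_a < med_b
            else "equal"
        )
        out[name] = {
            "retained_median": med_a,
            "non_retained_median": med_b,
            "p_value": float(p),
            "direction": direction,
        }
    return out
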