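"""Histone-mark peak enrichment near splice sites of retained introns.

Counts peaks overlapping the strand-oriented 5' splice-site window, the
intron body, and the 3' splice-site window, and compares retained vs
non-retained introns within host-gene expression quartiles so that an
apparent enrichment cannot be a mere expression-level artefact.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import IntronUnit
from .stats import mann_whitney_u


def _overlap_counts(
    starts: np.ndarray, ends: np.ndarray, zone_start: int, zone_end: int
) -> int:
    """Number of intervals overlapping [zone_start, zone_end); intervals are
    given as a start-sorted array and an independently sorted end array."""
    n = len(starts)
    before = np.searchsorted(ends, zone_start, side="right")  # end <= zone_start
    not_started = n - np.searchsorted(starts, zone_end, side="left")  # start >= zone_end
    return int(n - before - not_started)


def peak_counts_near_splice_sites(
    peaks: pd.DataFrame,
    introns: Sequence[IntronUnit],
    window: int = 200,
) -> pd.DataFrame:
    """Per-intron peak counts in the 5'SS ±window, intron body, and
    3'SS ±window zones (a peak overlapping two zones counts in each)."""
    if window <= 0:
        raise ValueError("window must be > 0")
    by_chrom: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for chrom, chunk in peaks.groupby("chrom"):
        starts = np.sort(chunk["start"].to_numpy())
        ends = np.sort(chunk["end"].to_numpy())
        by_chrom[chrom] = (starts, ends)
    rows = []
    for intron in introns:
        starts, ends = by_chrom.get(intron.chrom, (np.array([]), np.array([])))
        five, three = intron.splice_sites()
        rows.append(
            {
                "intron_id": intron.intron_id,
                "gene_id": intron.gene_id,
                "n_5ss": _overlap_counts(starts, ends, five - window, five + window),
                "n_body": _overlap_counts(starts, ends, intron.start, intron.end),
                "n_3ss": _overlap_counts(starts, ends, three - window, three + window),
            }
        )
    df = pd.DataFrame(rows)
    df["n_ss_total"] = df["n_5ss"] + df["n_3ss"]
    return df


def quartile_stratified_enrichment(
    peak_counts: pd.DataFrame,
    gene_expression: Mapping[str, float] | pd.Series,
    retained_labels: Mapping[str, bool] | pd.Series,
    statistic: str = "n_ss_total",
) -> pd.DataFrame:
    """Retained vs non-retained peak-count comparison per expression quartile.

    Genes with TPM > 0 are split into four quartiles (stable gene order
    breaks ties); within each quartile the per-intron counts of retained and
    non-retained introns are compared with a Mann–Whitney U test. Quartiles
    with fewer than two introns in either group are flagged and reported
    without a p-value.
    """
    expr = pd.Series(gene_expression, dtype=float)
    labels = pd.Series(retained_labels)
    df = peak_counts.copy()
    df["tpm"] = df["gene_id"].map(expr)
    if df["tpm"].isna().any():
        missing = df.loc[df["tpm"].isna(), "gene_id"].unique()[:3]
        raise ValueError(f"introns whose gene has no expression value: {list(missing)}")
    df["retained"] = df["intron_id"].map(labels).astype(bool)
    # quartile boundaries on gene-level TPM of expressed genes, stable order
    expressed = expr[expr > 0]
    ranks = expressed.rank(method="first")
    quartile = pd.qcut(ranks, 4, labels=["Q1", "Q2", "Q3", "Q4"])
    df = df[df["gene_id"].isin(quartile.index)]
    df["quartile"] = df["gene_id"].map(quartile)
    rows = []
    for q in ["Q1", "Q2", "Q3", "Q4"]:
        sub = df[df["quartile"] == q]
        ret = sub.loc[sub["retained"], statistic]
        non = sub.loc[~sub["retained"], statistic]
        row = {
            "quartile": q,
            "n_retained": len(ret),
            "n_non_retained": len(non),
            "retained_mean": ret.mean() if len(ret) else np.nan,
            "non_retained_mean": non.mean() if len(non) else np.nan,
            "p_value": np.nan,
            "flagged": False,
        }
        if len(ret) >= 2 and len(non) >= 2:
            _, row["p_value"] = mann_whitney_u(ret.to_numpy(), non.to_numpy())
        else:
            row["flagged"] = True
        rows.append(row)
    out = pd.DataFrame(rows)
    out["ratio"] = out["retained_mean"] / out["non_retained_mean"]
    return out
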