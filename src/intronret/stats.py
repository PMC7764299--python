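"""Differential statistics: size factors, NB Wald tests, BH adjustment,
differential IR, differential exon usage, and rank tests.

The two-group negative-binomial Wald test is shared machinery: gene-level
differential expression uses size factors as per-sample exposures, the
differential-IR test uses per-intron total splicing evidence
(intronic + junction counts) as exposure — so it tests a change in retention
fraction rather than raw intronic abundance — and differential exon usage
uses host-gene counts as exposure. Dispersion is a per-feature
method-of-moments estimate with a small floor; p-values use a t reference
with nA + nB − 2 degrees of freedom, which keeps the type-I error close to
nominal at the small group sizes the test is meant for.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

DISPERSION_FLOOR = 1e-4


def size_factors(counts: pd.DataFrame) -> pd.Series:
    """Median-of-ratios normalization factors (geometric-mean reference).

    Falls back to total-count scaling (with a warning) when no feature is
    nonzero in every sample.
    """
    if counts.shape[1] < 2:
        raise ValueError("need at least two samples")
    mat = counts.to_numpy(dtype=float)
    all_nonzero = (mat > 0).all(axis=1)
    if not all_nonzero.any():
        import logging

        logging.getLogger(__name__).warning(
            "no feature nonzero in all samples; using total-count scaling"
        )
        totals = mat.sum(axis=0)
        factors = totals / np.exp(np.mean(np.log(totals)))
    else:
        sub = mat[all_nonzero]
        log_geo = np.mean(np.log(sub), axis=1, keepdims=True)
        ratios = np.log(sub) - log_geo
        factors = np.exp(np.median(ratios, axis=0))
    return pd.Series(factors, index=counts.columns, name="size_factor")


def _check_groups(columns, groups) -> tuple[np.ndarray, np.ndarray, list[str]]:
    groups = pd.Series(groups, index=columns) if not isinstance(groups, pd.Series) else groups
    levels = list(pd.unique(groups))
    if len(levels) != 2:
        raise ValueError(f"need exactly two groups, got {levels}")
    a = (groups == levels[0]).to_numpy()
    b = (groups == levels[1]).to_numpy()
    if a.sum() < 2 or b.sum() < 2:
        raise ValueError("each group needs n >= 2")
    return a, b, levels


def _wald_core(
    counts: np.ndarray, exposures: np.ndarray, in_a: np.ndarray, in_b: np.ndarray
) -> pd.DataFrame:
    """Two-group NB Wald test of log(mean rate B / mean rate A).

    ``exposures`` has the same shape as ``counts`` (per-feature per-sample):
    the model is K_ij ~ NB(exposure_ij * m_g, alpha_i).
    """
    nA, nB = int(in_a.sum()), int(in_b.sum())
    eA, eB = exposures[:, in_a], exposures[:, in_b]
    kA, kB = counts[:, in_a], counts[:, in_b]
    sA, sB = eA.sum(axis=1), eB.sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        mA = np.where(sA > 0, kA.sum(axis=1) / np.maximum(sA, 1e-300), np.nan)
        mB = np.where(sB > 0, kB.sum(axis=1) / np.maximum(sB, 1e-300), np.nan)
        # method-of-moments dispersion from normalized counts, pooled within groups
        yA = np.where(eA > 0, kA / np.maximum(eA, 1e-300), np.nan)
        yB = np.where(eB > 0, kB / np.maximum(eB, 1e-300), np.nan)
        vA = np.nanvar(yA, axis=1, ddof=1)
        vB = np.nanvar(yB, axis=1, ddof=1)
        v = ((nA - 1) * vA + (nB - 1) * vB) / (nA + nB - 2)
        m = (nA * mA + nB * mB) / (nA + nB)
        inv_e = np.nanmean(np.where(exposures > 0, 1.0 / np.maximum(exposures, 1e-300), np.nan), axis=1)
        alpha = np.maximum((v - m * inv_e) / np.maximum(m, 1e-300) ** 2, DISPERSION_FLOOR)
        varA = (sA * mA + alpha * (eA**2).sum(axis=1) * mA**2) / np.maximum(sA, 1e-300) ** 2
        varB = (sB * mB + alpha * (eB**2).sum(axis=1) * mB**2) / np.maximum(sB, 1e-300) ** 2
        # continuity guard: a zero group mean gets half a count of evidence
        mA_safe = np.maximum(mA, 0.5 / np.maximum(sA, 1e-300))
        mB_safe = np.maximum(mB, 0.5 / np.maximum(sB, 1e-300))
        se = np.sqrt(varA / mA_safe**2 + varB / mB_safe**2)
        se = np.maximum(se, 1e-12)
        log_fc = np.log(mA_safe) - np.log(mB_safe)  # first-named over second
        stat = log_fc / se
    p = 2 * sps.t.sf(np.abs(stat), df=nA + nB - 2)
    all_zero = (counts.sum(axis=1) == 0) | ~np.isfinite(stat)
    stat = np.where(all_zero, 0.0, stat)
    p = np.where(all_zero, 1.0, p)
    log2_fc = np.where(all_zero, 0.0, log_fc / np.log(2))
    return pd.DataFrame(
        {
            "base_mean": m,
            "log2_fc": log2_fc,
            "stat": stat,
            "p_value": p,
            "flagged": all_zero,
        }
    )


def nb_wald_test(
    counts: pd.DataFrame,
    groups,
    sf: pd.Series | None = None,
) -> pd.DataFrame:
    """Per-feature two-group NB Wald test on a count matrix.

    ``log2_fc`` is the log2 fold change of the first-named group over the
    second (e.g. diagnosis over control when groups name diagnosis first).
    All-zero features are flagged with p = 1, log2_fc = 0. q-values
    are BH-adjusted within the tested family (flagged features excluded).
    """
    in_a, in_b, levels = _check_groups(counts.columns, groups)
    sf = size_factors(counts) if sf is None else sf
    exposures = np.broadcast_to(
        sf.reindex(counts.columns).to_numpy(dtype=float), counts.shape
    )
    res = _wald_core(counts.to_numpy(dtype=float), exposures, in_a, in_b)
    res.insert(0, "feature_id", counts.index)
    res["q_value"] = _bh_with_flags(res["p_value"].to_numpy(), res["flagged"].to_numpy())
    res.attrs["groups"] = levels
    return res


def differential_ir(
    intronic: pd.DataFrame,
    junction: pd.DataFrame,
    groups,
) -> pd.DataFrame:
    """Differential intron retention between two groups.

    Tests intronic counts with per-sample total evidence (intronic +
    junction) as exposure, so the null is "same retention fraction".
    Reports ``delta_ir`` = mean per-sample IR ratio (group A − group B,
    first-named minus second). Introns with zero total evidence in either
    group are flagged and excluded from the BH family.
    """
    if not intronic.index.equals(junction.index) or not intronic.columns.equals(junction.columns):
        raise ValueError("intronic and junction matrices must share features and samples")
    in_a, in_b, levels = _check_groups(intronic.columns, groups)
    k = intronic.to_numpy(dtype=float)
    expo = k + junction.to_numpy(dtype=float)
    res = _wald_core(k, expo, in_a, in_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(expo > 0, k / np.maximum(expo, 1e-300), np.nan)
    mean_a = np.nanmean(ratio[:, in_a], axis=1)
    mean_b = np.nanmean(ratio[:, in_b], axis=1)
    delta = mean_a - mean_b
    no_evidence = (expo[:, in_a].sum(axis=1) == 0) | (expo[:, in_b].sum(axis=1) == 0)
    res.insert(0, "feature_id", intronic.index)
    res["delta_ir"] = np.where(no_evidence, np.nan, delta)
    res["flagged"] = res["flagged"].to_numpy() | no_evidence
    res.loc[res["flagged"], ["stat"]] = 0.0
    res.loc[res["flagged"], ["p_value"]] = 1.0
    res["q_value"] = _bh_with_flags(res["p_value"].to_numpy(), res["flagged"].to_numpy())
    res.attrs["groups"] = levels
    return res


def deu_usage(with_exon: float, without_exon: float) -> float:
    """Relative exon usage: with / (with + without)."""
    denom = with_exon + without_exon
    if denom <= 0:
        raise ValueError("usage undefined: with + without must be > 0")
    return with_exon / denom


def differential_exon_usage(
    exon_counts: pd.DataFrame,
    gene_counts: pd.DataFrame,
    exon_to_gene: pd.Series,
    groups,
) -> pd.DataFrame:
    """Differential exon usage between two groups.

    Per exon, usage = exon count / gene count (transcripts with the exon
    over all transcripts); the test is the NB Wald test on exon counts with
    host-gene counts as exposure. ``direction`` is the sign of the usage
    change in the first-named condition ("up" when usage is higher in the
    first group).
    """
    in_a, in_b, levels = _check_groups(exon_counts.columns, groups)
    genes = exon_to_gene.reindex(exon_counts.index)
    if genes.isna().any():
        missing = list(exon_counts.index[genes.isna()])[:3]
        raise ValueError(f"exons without gene mapping: {missing}")
    gmat = gene_counts.loc[genes.to_numpy(), exon_counts.columns].to_numpy(dtype=float)
    emat = exon_counts.to_numpy(dtype=float)
    bad = emat > gmat
    if bad.any():
        exon = exon_counts.index[bad.any(axis=1)][0]
        raise ValueError(f"exon count exceeds gene count for exon {exon!r}")
    res = _wald_core(emat, gmat, in_a, in_b)
    with np.errstate(divide="ignore", invalid="ignore"):
        usage = np.where(gmat > 0, emat / np.maximum(gmat, 1e-300), np.nan)
    usage_a = np.nanmean(usage[:, in_a], axis=1)
    usage_b = np.nanmean(usage[:, in_b], axis=1)
    res.insert(0, "feature_id", exon_counts.index)
    res["gene_id"] = genes.to_numpy()
    res["usage_a"] = usage_a
    res["usage_b"] = usage_b
    diff = usage_a - usage_b  # first-named condition minus second
    res["direction"] = np.select([diff > 0, diff < 0], ["up", "down"], default="none")
    # constitutive exons (usage 1 in every sample) carry no usage signal
    constitutive = np.nanmin(usage, axis=1) >= 1.0
    res.loc[constitutive, ["stat"]] = 0.0
    res.loc[constitutive, ["p_value"]] = 1.0
    res.loc[constitutive, ["direction"]] = "none"
    res["flagged"] = res["flagged"].to_numpy() | constitutive
    res["q_value"] = _bh_with_flags(res["p_value"].to_numpy(), res["flagged"].to_numpy())
    res.attrs["groups"] = levels
    return res


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, order-preserving on input indices."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _bh_with_flags(p: np.ndarray, flagged: np.ndarray) -> np.ndarray:
    q = np.full(p.shape, np.nan)
    keep = ~flagged
    if keep.any():
        q[keep] = bh_adjust(p[keep])
    return q


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Mann–Whitney U test.

    Exact U distribution for small groups (both n <= 8, no ties), normal
    approximation with tie correction otherwise. Returns (U of the first
    group, p).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    ties = len(np.unique(np.concatenate([a, b]))) < a.size + b.size
    method = "exact" if (a.size <= 8 and b.size <= 8 and not ties) else "asymptotic"
    res = sps.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(res.pvalue)
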