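"""WGBS-style methylation analysis: simplified DMR calling, DMR density over
gene features, and splice-site-anchored CpG methylation metaprofiles.

The DMR caller is a transparent Fisher-plus-merge procedure: per-CpG counts
are pooled within each group and compared with Fisher's exact test, BH is
applied across CpGs, and significant CpGs with a consistent direction are
merged into regions. It is designed for planted-region recovery, not as a
reimplementation of an HMM-based WGBS pipeline.

Metaprofiles align CpGs to three strand-oriented anchors — the 5' splice
site, the intron centre, and the 3' splice site — and average methylated /
total counts per offset, separately for retained and non-retained introns.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

from .annotation import FeatureMap, IntronUnit, FEATURE_LABELS
from .simulate import _rng
from .stats import bh_adjust

ANCHORS = ("5ss", "centre", "3ss")


@dataclass
class DMRParams:
    min_cpg: int = 5
    min_delta: float = 0.1
    alpha: float = 0.05
    max_gap: int = 250


def _pool_tracks(tracks: Sequence[pd.DataFrame]) -> pd.DataFrame:
    pooled = (
        pd.concat(tracks, ignore_index=True)
        .groupby(["chrom", "pos"], as_index=False)[["methylated", "total"]]
        .sum()
    )
    return pooled


def call_dmrs(
    tracks_group_a: Sequence[pd.DataFrame],
    tracks_group_b: Sequence[pd.DataFrame],
    params: DMRParams | None = None,
) -> pd.DataFrame:
    """Call differentially methylated regions between two groups of tracks.

    Returns a DataFrame (chrom, start, end, n_sig_cpg, delta, direction);
    delta is the coverage-weighted mean per-CpG methylation difference
    (group A − group B), a proportion in [−1, 1].
    """
    params = params or DMRParams()
    if not tracks_group_a or not tracks_group_b:
        raise ValueError("each group needs at least one methylation track")
    a = _pool_tracks(tracks_group_a).rename(
        columns={"methylated": "meth_a", "total": "tot_a"}
    )
    b = _pool_tracks(tracks_group_b).rename(
        columns={"methylated": "meth_b", "total": "tot_b"}
    )
    merged = a.merge(b, on=["chrom", "pos"], how="inner")
    if merged.empty:
        raise ValueError("groups share no CpG positions")
    merged = merged[(merged["tot_a"] > 0) & (merged["tot_b"] > 0)].reset_index(drop=True)
    level_a = merged["meth_a"] / merged["tot_a"]
    level_b = merged["meth_b"] / merged["tot_b"]
    merged["delta"] = level_a - level_b
    p = np.empty(len(merged))
    ma = merged["meth_a"].to_numpy()
    ua = (merged["tot_a"] - merged["meth_a"]).to_numpy()
    mb = merged["meth_b"].to_numpy()
    ub = (merged["tot_b"] - merged["meth_b"]).to_numpy()
    for i in range(len(merged)):
        _, p[i] = sps.fisher_exact([[ma[i], ua[i]], [mb[i], ub[i]]])
    merged["q"] = bh_adjust(p)
    sig = merged[
        (merged["q"] < params.alpha) & (merged["delta"].abs() >= params.min_delta)
    ]
    regions = []
    for chrom, chunk in sig.groupby("chrom"):
        chunk = chunk.sort_values("pos")
        current: list[pd.Series] = []
        for _, row in chunk.iterrows():
            if current and (
                row["pos"] - current[-1]["pos"] > params.max_gap
                or np.sign(row["delta"]) != np.sign(current[-1]["delta"])
            ):
                regions.append(_finish_region(chrom, current, params))
                current = []
            current.append(row)
        if current:
            regions.append(_finish_region(chrom, current, params))
    regions = [r for r in regions if r is not None]
    cols = ["chrom", "start", "end", "n_sig_cpg", "delta", "direction"]
    if not regions:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(regions)[cols].sort_values(["chrom", "start"]).reset_index(drop=True)


def _finish_region(chrom: str, rows: list[pd.Series], params: DMRParams):
    if len(rows) < params.min_cpg:
        return None
    df = pd.DataFrame(rows)
    weights = df["tot_a"] + df["tot_b"]
    delta = float(np.average(df["delta"], weights=weights))
    return {
        "chrom": chrom,
        "start": int(df["pos"].min()),
        "end": int(df["pos"].max()) + 1,
        "n_sig_cpg": len(df),
        "delta": delta,
        "direction": "hyper" if delta > 0 else "hypo",
    }


def dmr_feature_density(dmrs: pd.DataFrame, feature_map: FeatureMap) -> pd.DataFrame:
    """Count DMRs per gene-feature label (by region midpoint) and report the
    density per megabase of that label."""
    totals = feature_map.total_bp()
    counts = dict.fromkeys(FEATURE_LABELS, 0)
    for _, dmr in dmrs.iterrows():
        mid = int((dmr["start"] + dmr["end"]) // 2)
        counts[feature_map.label_at(dmr["chrom"], mid)] += 1
    rows = []
    for label in FEATURE_LABELS:
        mb = totals[label] / 1e6
        rows.append(
            {
                "feature": label,
                "count": counts[label],
                "total_bp": totals[label],
                "density_per_mb": counts[label] / mb if mb > 0 else np.nan,
            }
        )
    return pd.DataFrame(rows)


def _anchor_offsets(
    intron: IntronUnit, window: int, min_centre: int = 20
) -> list[tuple[str, int, int]]:
    """(anchor, genomic_pos_start, transcription-oriented offset base) spans.

    Yields tuples (anchor, genomic position, offset) for every base of the
    three anchor windows. Offsets run in transcriptional direction:
    negative = upstream of the anchor point.
    """
    spans = []
    length = intron.length
    if intron.strand == "+":
        five, three = intron.start, intron.end
        sign = 1
    else:
        five, three = intron.end, intron.start
        sign = -1
    for anchor, centre_pos in (("5ss", five), ("3ss", three)):
        for off in range(-window, window):
            spans.append((anchor, centre_pos + sign * off, off))
    # centre window: middle 200 bp, shrunk to the region between the two
    # splice-site windows for short introns; dropped when < min_centre
    centre_w = 200
    if length >= 2 * window + centre_w:
        inner = centre_w
    else:
        inner = length - 2 * window
    if inner >= min_centre:
        mid = (intron.start + intron.end) // 2
        for off in range(-(inner // 2), inner - inner // 2):
            spans.append(("centre", mid + sign * off, off))
    return spans


def splice_anchor_profile(
    tracks: Sequence[pd.DataFrame],
    retained: Sequence[IntronUnit],
    non_retained: Sequence[IntronUnit],
    window: int = 200,
) -> pd.DataFrame:
    """Splice-site-anchored methylation metaprofiles for retained vs
    non-retained introns.

    Returns long-form rows (anchor, offset, group, meth, coverage) where
    ``meth`` is sum(methylated)/sum(total) over all CpGs at that
    strand-oriented offset across introns and samples, and ``coverage`` is
    the summed total count (zero-weight offsets keep coverage 0 rather than
    reporting a methylation of 0).
    """
    if not retained:
        raise ValueError("retained intron list is empty")
    if not non_retained:
        raise ValueError("non_retained intron list is empty")
    by_chrom = _indexed_tracks(tracks)
    rows = []
    for group, introns in (("retained", retained), ("non_retained", non_retained)):
        acc: dict[tuple[str, int], list[float]] = {}
        for intron in introns:
            table = by_chrom.get(intron.chrom)
            if table is None:
                continue
            anchors, positions, offsets = _anchor_offset_arrays(intron, window)
            found, meths, tots = _lookup(table, positions)
            for i in np.flatnonzero(found):
                cell = acc.setdefault((anchors[i], int(offsets[i])), [0.0, 0.0])
                cell[0] += meths[i]
                cell[1] += tots[i]
        for (anchor, off), (meth, tot) in acc.items():
            rows.append(
                {
                    "anchor": anchor,
                    "offset": off,
                    "group": group,
                    "meth": meth / tot if tot > 0 else np.nan,
                    "coverage": tot,
                }
            )
    return (
        pd.DataFrame(rows)
        .sort_values(["group", "anchor", "offset"])
        .reset_index(drop=True)
    )


def _indexed_tracks(
    tracks: Sequence[pd.DataFrame],
) -> dict[str, tuple[np.ndarray, np.ndarray, np.ndarray]]:
    """Pool tracks and index per chromosome as (sorted pos, meth, total)."""
    pooled = _pool_tracks(tracks)
    out = {}
    for chrom, chunk in pooled.groupby("chrom"):
        chunk = chunk.sort_values("pos")
        out[chrom] = (
            chunk["pos"].to_numpy(),
            chunk["methylated"].to_numpy(dtype=float),
            chunk["total"].to_numpy(dtype=float),
        )
    return out


def _lookup(
    table: tuple[np.ndarray, np.ndarray, np.ndarray], positions: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    pos, meth, tot = table
    if len(pos) == 0:
        empty = np.zeros(len(positions))
        return empty.astype(bool), empty, empty
    idx = np.searchsorted(pos, positions)
    idx = np.clip(idx, 0, len(pos) - 1)
    found = pos[idx] == positions
    return found, meth[idx], tot[idx]


def _anchor_offset_arrays(
    intron: IntronUnit, window: int
) -> tuple[list[str], np.ndarray, np.ndarray]:
    spans = _anchor_offsets(intron, window)
    anchors = [a for a, _, _ in spans]
    positions = np.array([p for _, p, _ in spans], dtype=int)
    offsets = np.array([o for _, _, o in spans], dtype=int)
    return anchors, positions, offsets


def _per_intron_anchor_counts(
    tracks: Sequence[pd.DataFrame],
    introns: Sequence[IntronUnit],
    group: str,
    window: int,
) -> pd.DataFrame:
    by_chrom = _indexed_tracks(tracks)
    rows = []
    for intron in introns:
        table = by_chrom.get(intron.chrom)
        if table is None:
            continue
        sums = {a: [0.0, 0.0] for a in ANCHORS}
        anchors, positions, _ = _anchor_offset_arrays(intron, window)
        found, meths, tots = _lookup(table, positions)
        for i in np.flatnonzero(found):
            sums[anchors[i]][0] += meths[i]
            sums[anchors[i]][1] += tots[i]
        for anchor, (meth, tot) in sums.items():
            if tot > 0:
                rows.append(
                    {
                        "intron_id": intron.intron_id,
                        "anchor": anchor,
                        "group": group,
                        "methylated": meth,
                        "total": tot,
                    }
                )
    return pd.DataFrame(rows)


def profile_group_test(
    tracks: Sequence[pd.DataFrame],
    retained: Sequence[IntronUnit],
    non_retained: Sequence[IntronUnit],
    window: int = 200,
    method: str = "glm",
    n_permutations: int = 500,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-anchor test of retained vs non-retained methylation.

    ``method="glm"``: binomial GLM of per-intron aggregated methylated/total
    on the group indicator; p from the group-coefficient Wald test.
    ``method="permutation"``: intron labels are permuted and the difference
    of pooled methylation levels is used as the statistic (calibration
    fallback). Returns a DataFrame (anchor, p_value, effect) where effect is
    pooled retained − non-retained methylation.
    """
    if not retained or not non_retained:
        raise ValueError("both intron groups must be non-empty")
    counts = pd.concat(
        [
            _per_intron_anchor_counts(tracks, retained, "retained", window),
            _per_intron_anchor_counts(tracks, non_retained, "non_retained", window),
        ],
        ignore_index=True,
    )
    rows = []
    rng = _rng(seed, "profile_perm")
    for anchor in ANCHORS:
        sub = counts[counts["anchor"] == anchor]
        if sub.empty or sub["group"].nunique() < 2:
            rows.append({"anchor": anchor, "p_value": np.nan, "effect": np.nan})
            continue
        g = (sub["group"] == "retained").to_numpy(dtype=float)
        meth = sub["methylated"].to_numpy()
        tot = sub["total"].to_numpy()
        pooled_r = meth[g == 1].sum() / tot[g == 1].sum()
        pooled_n = meth[g == 0].sum() / tot[g == 0].sum()
        effect = pooled_r - pooled_n
        if method == "glm":
            exog = sm.add_constant(g)
            endog = np.column_stack([meth, tot - meth])
            fit = sm.GLM(endog, exog, family=sm.families.Binomial()).fit()
            p = float(fit.pvalues[1])
        elif method == "permutation":
            obs = abs(effect)
            hits = 0
            for _ in range(n_permutations):
                perm = rng.permutation(g)
                pr = meth[perm == 1].sum() / tot[perm == 1].sum()
                pn = meth[perm == 0].sum() / tot[perm == 0].sum()
                if abs(pr - pn) >= obs:
                    hits += 1
            p = (hits + 1) / (n_permutations + 1)
        else:
            raise ValueError(f"unknown method {method!r}")
        rows.append({"anchor": anchor, "p_value": p, "effect": effect})
    return pd.DataFrame(rows)
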