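"""Intron retention quantification from spliced alignments.

The IR ratio of an intron estimates the fraction of the gene's transcripts
that retain it:

    ir_ratio = intronic_depth / (intronic_depth + junction_count)

where ``junction_count`` is the number of reads whose splice gap matches the
intron boundaries exactly, and ``intronic_depth`` is the median per-base
depth over the intron's measurable positions (bases not covered by any
annotated exon), counting only contiguous aligned blocks.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .annotation import IntronUnit
from .simulate import AlignmentRecord, _rng


@dataclass
class IRThresholds:
    """Event-calling thresholds: an intron is an IR event in a sample when
    ir_ratio >= t_ratio, intronic_depth >= t_depth and
    junction_count + intronic_depth >= t_total."""

    t_ratio: float = 0.1
    t_depth: float = 3.0
    t_total: float = 10.0


@dataclass
class IRMeasurement:
    intron_id: str
    sample: str
    junction_count: int
    intronic_depth: float
    ir_ratio: float  # NaN when undefined
    ok: bool
    reason: str = ""


@dataclass
class SampleIRSummary:
    sample: str
    condition: str
    n_ir_events: int
    depth_used: int  # fragments the sample was measured at


class _AlignmentIndex:
    """Depth arrays and an exact-gap counter built in one pass over reads."""

    def __init__(self, alignments: Iterable[AlignmentRecord]):
        self.junctions: Counter[tuple[str, int, int]] = Counter()
        deltas: dict[str, dict[int, int]] = {}
        for rec in alignments:
            d = deltas.setdefault(rec.chrom, {})
            for s, e in rec.blocks:
                d[s] = d.get(s, 0) + 1
                d[e] = d.get(e, 0) - 1
            for gs, ge in rec.gaps():
                self.junctions[(rec.chrom, gs, ge)] += 1
        # sorted breakpoint representation -> step function of depth
        self._steps: dict[str, tuple[np.ndarray, np.ndarray]] = {}
        for chrom, d in deltas.items():
            pos = np.array(sorted(d), dtype=int)
            depth = np.cumsum([d[p] for p in pos])
            self._steps[chrom] = (pos, depth)

    def depth_profile(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Per-base depth over [start, end)."""
        out = np.zeros(end - start, dtype=float)
        if chrom not in self._steps:
            return out
        pos, depth = self._steps[chrom]
        grid = np.arange(start, end)
        idx = np.searchsorted(pos, grid, side="right") - 1
        valid = idx >= 0
        out[valid] = depth[idx[valid]]
        return out


def measure_intron(
    alignments: Iterable[AlignmentRecord] | _AlignmentIndex,
    intron: IntronUnit,
    sample: str = "",
) -> IRMeasurement:
    """Measure one intron against a set of alignments."""
    index = (
        alignments
        if isinstance(alignments, _AlignmentIndex)
        else _AlignmentIndex(alignments)
    )
    return _measure(index, intron, sample)


def _measure(index: _AlignmentIndex, intron: IntronUnit, sample: str) -> IRMeasurement:
    if intron.measurable_length == 0:
        return IRMeasurement(intron.intron_id, sample, 0, 0.0, float("nan"), False, "fully_excluded")
    junction_count = index.junctions.get((intron.chrom, intron.start, intron.end), 0)
    profile = index.depth_profile(intron.chrom, intron.start, intron.end)
    mask = np.ones(intron.length, dtype=bool)
    for s, e in intron.exclusion_zones:
        mask[s - intron.start : e - intron.start] = False
    depth = float(np.median(profile[mask]))
    denom = depth + junction_count
    if denom > 0:
        ratio = depth / denom
        return IRMeasurement(intron.intron_id, sample, junction_count, depth, ratio, True)
    return IRMeasurement(
        intron.intron_id, sample, junction_count, depth, float("nan"), False, "no_evidence"
    )


def measure_introns(
    alignments: Iterable[AlignmentRecord],
    introns: Sequence[IntronUnit],
    sample: str = "",
) -> pd.DataFrame:
    """Measure every intron in one pass; returns the per-sample IR table."""
    index = _AlignmentIndex(alignments)
    rows = [_measure(index, intron, sample).__dict__ for intron in introns]
    return pd.DataFrame(rows)


def call_ir_events(
    measurements: pd.DataFrame,
    thresholds: IRThresholds | None = None,
    sample: str = "",
    condition: str = "",
    depth_used: int = 0,
) -> SampleIRSummary:
    """Count IR events (threshold-passing introns) for one sample."""
    thresholds = thresholds or IRThresholds()
    if len(measurements) == 0:
        import logging

        logging.getLogger(__name__).warning("no measurements for sample %r", sample)
        return SampleIRSummary(sample, condition, 0, depth_used)
    m = measurements
    passing = (
        m["ok"]
        & (m["ir_ratio"] >= thresholds.t_ratio)
        & (m["intronic_depth"] >= thresholds.t_depth)
        & (m["junction_count"] + m["intronic_depth"] >= thresholds.t_total)
    )
    if not sample and "sample" in m:
        uniq = m["sample"].unique()
        sample = uniq[0] if len(uniq) == 1 else ""
    return SampleIRSummary(sample, condition, int(passing.sum()), depth_used)


def subsample_alignments(
    alignments: Sequence[AlignmentRecord],
    target_fragments: int,
    seed: int = 0,
) -> list[AlignmentRecord]:
    """Uniform subsample without replacement to exactly ``target_fragments``.

    Deterministic for a fixed seed; output sorted by coordinate.
    """
    n = len(alignments)
    if target_fragments > n:
        raise ValueError(
            f"target_fragments ({target_fragments}) exceeds available fragments ({n})"
        )
    rng = _rng(seed, "subsample")
    keep = rng.choice(n, size=target_fragments, replace=False)
    picked = [alignments[i] for i in sorted(keep)]
    picked.sort(key=lambda r: (r.chrom, r.start, r.end, r.read_id))
    return picked
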