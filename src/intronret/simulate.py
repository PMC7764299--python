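"""Truth-known synthetic cohort generator.

Emulates the statistical structure of a three-condition leukaemia cohort
(diagnosis / remission / control): per-gene negative-binomial expression,
per-intron retention fractions that are elevated at diagnosis and at least
as high in remission, CpG methylation dips over retained introns, and
histone-mark peak enrichment near retained-intron splice sites.

Everything is deterministic under a fixed seed, and the planted parameters
(:class:`SyntheticTruth`) are kept alongside the generated data so every
pipeline stage can be tested for parameter recovery without any external
download.

Fragment model
--------------
Reads are single-end, fixed length ``L``. For each gene a fragment count is
drawn from NB(depth·µ_g, α_g). Each fragment samples a transcript molecule —
retained or spliced per intron with the condition's retention fraction — with
probability proportional to molecule abundance × number of start positions,
then a uniform start position on that molecule. Under this model the
fraction of boundary-spanning fragments that retain intron *i* is exactly
r_i, which is what the downstream IR-ratio estimator measures.
"""

from __future__ import annotations

import hashlib
import itertools
import re
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .annotation import Gene, GenomeAnnotation, IntronUnit, Transcript, derive_intron_units

CONDITIONS = ("diagnosis", "remission", "control")


@dataclass(frozen=True)
class CohortConfig:
    """Study-design parameters of the synthetic cohort.

    Defaults describe a small but realistic bulk RNA-seq contrast: 20 genes,
    2 introns each, 10/10/6 samples, NB dispersion 0.1, a quarter of introns
    with retention elevated by Δr = 0.25 at diagnosis, methylation dips of
    0.3 over retained introns, and 4-fold peak enrichment at their splice
    sites.
    """

    n_genes: int = 20
    introns_per_gene: int = 2
    exon_length: int = 300
    intron_length: int = 800
    affected_intron_length: int = 400
    intergenic_gap: int = 2000
    n_affected: int = 10
    base_retention: float = 0.05
    delta_r: float = 0.25
    remission_boost: float = 0.05
    n_samples: dict[str, int] = field(
        default_factory=lambda: {"diagnosis": 10, "remission": 10, "control": 6}
    )
    mu_range: tuple[float, float] = (100.0, 1000.0)
    nb_dispersion: float = 0.1
    read_length: int = 100
    # host genes of the first n_inverse affected introns also change
    # expression at diagnosis (opposite direction to their IR change),
    # planting inverse IR/expression relationships; kept a minority of genes
    # so median-of-ratios normalization stays valid
    n_inverse: int = 5
    expression_log2fc: float = -2.0
    m0: float = 0.8
    dip_depth: float = 0.3
    # extent of the dip beyond the intron body; 0 keeps exonic flanks at m0
    # so splice-site profiles show the dip strictly inside the intron
    dip_flank: int = 0
    dip_r_threshold: float = 0.2
    mean_coverage: float = 30.0
    lambda_near: float = 0.02  # peaks per bp near retained splice sites
    lambda_bg: float = 0.005
    peak_width: int = 50
    peak_window: int = 200
    gc_background: float = 0.45
    gc_affected_intron: float = 0.60

    def validate(self) -> None:
        if not 0 <= self.base_retention <= 1:
            raise ValueError("base_retention must be in [0, 1]")
        if not 0 <= self.base_retention + self.delta_r + self.remission_boost <= 1:
            raise ValueError("retention fractions must stay in [0, 1]")
        if not 0 <= self.dip_depth <= self.m0 <= 1:
            raise ValueError("need 0 <= dip_depth <= m0 <= 1")
        if self.mu_range[0] <= 0:
            raise ValueError("expression means must be positive")
        if self.nb_dispersion <= 0:
            raise ValueError("NB dispersion must be positive")
        if self.lambda_bg < 0 or self.lambda_near < self.lambda_bg:
            raise ValueError("need lambda_near >= lambda_bg >= 0")
        if self.n_affected > self.n_genes * self.introns_per_gene:
            raise ValueError("n_affected exceeds intron count")
        if self.exon_length * (self.introns_per_gene + 1) < self.read_length:
            raise ValueError("gene spliced form shorter than read length")


@dataclass
class AlignmentRecord:
    """A single-end aligned fragment as sorted, non-overlapping blocks.

    Gaps between blocks are splice junctions. ``retained`` records, for the
    simulator's own output, which introns the source molecule retained
    (truth labels for oracle tests); it is empty for records read from SAM.
    """

    read_id: str
    sample: str
    chrom: str
    blocks: tuple[tuple[int, int], ...]
    strand: str = "+"
    retained: tuple[str, ...] = ()

    @property
    def start(self) -> int:
        return self.blocks[0][0]

    @property
    def end(self) -> int:
        return self.blocks[-1][1]

    def gaps(self) -> list[tuple[int, int]]:
        return [(e1, s2) for (_, e1), (s2, _) in zip(self.blocks, self.blocks[1:])]


@dataclass
class SyntheticTruth:
    """Planted ground truth for the synthetic cohort."""

    config: CohortConfig
    genome: dict[str, str]
    annotation: GenomeAnnotation
    introns: list[IntronUnit]
    # retention fraction per (intron_id, condition)
    retention: pd.DataFrame  # index intron_id, columns CONDITIONS
    affected_introns: list[str]
    inverse_genes: list[str]
    gene_mu: pd.DataFrame  # index gene_id, columns CONDITIONS
    gene_dispersion: pd.Series
    sample_sheet: pd.DataFrame  # columns: sample, condition
    seed: int

    def condition_of(self, sample: str) -> str:
        row = self.sample_sheet.loc[self.sample_sheet["sample"] == sample]
        if row.empty:
            raise KeyError(f"unknown sample {sample!r}")
        return str(row["condition"].iloc[0])

    def introns_of_gene(self, gene_id: str) -> list[IntronUnit]:
        return [iv for iv in self.introns if iv.gene_id == gene_id]

    def retained_intron_ids(self, condition: str, threshold: float | None = None) -> list[str]:
        thr = self.config.dip_r_threshold if threshold is None else threshold
        col = self.retention[condition]
        return list(col.index[col >= thr])


def _rng(seed: int, *salt) -> np.random.Generator:
    """Stage-salted generator: deterministic across processes for a fixed seed."""
    return np.random.default_rng(np.random.SeedSequence((seed, *map(_hash32, salt))))


def _hash32(x) -> int:
    digest = hashlib.sha256(str(x).encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


def build_truth(config: CohortConfig | None = None, seed: int = 0) -> SyntheticTruth:
    """Construct the planted cohort truth: genome, annotation, parameters.

    Deterministic for a fixed seed. A configurable subset of introns gets
    r_diagnosis = r_control + Δr and r_remission = r_diagnosis +
    remission_boost; affected introns are shorter and GC-richer than
    background, mirroring the intrinsic features of retained introns.
    """
    config = config or CohortConfig()
    config.validate()
    rng = _rng(seed, "truth")

    n_introns = config.n_genes * config.introns_per_gene
    # affected introns spread across genes: first intron of the first
    # n_affected genes, then second intron of further genes, and so on
    order = [
        g * config.introns_per_gene + k
        for k in range(config.introns_per_gene)
        for g in range(config.n_genes)
    ]
    affected_idx = set(order[: config.n_affected])

    genes: dict[str, Gene] = {}
    chrom = "chr1"
    seq_parts: list[str] = []
    pos = 0
    intron_meta: list[tuple[str, bool]] = []  # (intron_id, affected) in genome order

    def random_seq(length: int, gc: float, gen: np.random.Generator) -> str:
        p_gc = gc / 2
        p_at = (1 - gc) / 2
        return "".join(
            gen.choice(list("ACGT"), size=length, p=[p_at, p_gc, p_gc, p_at])
        )

    intron_counter = 0
    for g in range(config.n_genes):
        gene_id = f"G{g+1:03d}"
        strand = "+" if g % 2 == 0 else "-"
        seq_parts.append(random_seq(config.intergenic_gap, config.gc_background, rng))
        pos += config.intergenic_gap
        exons: list[tuple[int, int]] = []
        for k in range(config.introns_per_gene + 1):
            exons.append((pos, pos + config.exon_length))
            seq_parts.append(random_seq(config.exon_length, 0.5, rng))
            pos += config.exon_length
            if k < config.introns_per_gene:
                affected = intron_counter in affected_idx
                ilen = (
                    config.affected_intron_length if affected else config.intron_length
                )
                igc = config.gc_affected_intron if affected else config.gc_background
                istart = pos
                seq_parts.append(random_seq(ilen, igc, rng))
                pos += ilen
                intron_meta.append((f"{gene_id}:{chrom}:{istart}-{pos}", affected))
                intron_counter += 1
        gene = Gene(gene_id, chrom, strand)
        gene.transcripts[f"{gene_id}.t1"] = Transcript(f"{gene_id}.t1", exons)
        genes[gene_id] = gene
    seq_parts.append(random_seq(config.intergenic_gap, config.gc_background, rng))
    pos += config.intergenic_gap

    genome = {chrom: "".join(seq_parts)}
    annotation = GenomeAnnotation(genes=genes, chrom_lengths={chrom: pos})
    introns = derive_intron_units(annotation, genome)
    assert len(introns) == n_introns

    affected_ids = [iid for iid, aff in intron_meta if aff]
    retention = pd.DataFrame(
        config.base_retention,
        index=[iv.intron_id for iv in introns],
        columns=list(CONDITIONS),
        dtype=float,
    )
    retention.loc[affected_ids, "diagnosis"] = config.base_retention + config.delta_r
    retention.loc[affected_ids, "remission"] = (
        config.base_retention + config.delta_r + config.remission_boost
    )

    mu_base = np.exp(
        rng.uniform(np.log(config.mu_range[0]), np.log(config.mu_range[1]), config.n_genes)
    )
    gene_ids = sorted(genes)
    gene_mu = pd.DataFrame(
        {c: mu_base for c in CONDITIONS}, index=gene_ids, dtype=float
    )
    inverse_genes = sorted({iid.split(":")[0] for iid in affected_ids})[: config.n_inverse]
    gene_mu.loc[inverse_genes, "diagnosis"] *= 2.0 ** config.expression_log2fc
    gene_dispersion = pd.Series(config.nb_dispersion, index=gene_ids, dtype=float)

    samples = []
    for cond in CONDITIONS:
        for i in range(config.n_samples.get(cond, 0)):
            samples.append({"sample": f"{cond[:3]}_{i+1:02d}", "condition": cond})
    sample_sheet = pd.DataFrame(samples)

    return SyntheticTruth(
        config=config,
        genome=genome,
        annotation=annotation,
        introns=introns,
        retention=retention,
        affected_introns=affected_ids,
        inverse_genes=inverse_genes,
        gene_mu=gene_mu,
        gene_dispersion=gene_dispersion,
        sample_sheet=sample_sheet,
        seed=seed,
    )


def _transcript_forms(
    gene: Gene, introns: Sequence[IntronUnit]
) -> list[tuple[tuple[bool, ...], list[tuple[int, int]]]]:
    """All retention-status vectors with their genomic block layouts."""
    tx = next(iter(gene.transcripts.values()))
    forms = []
    for status in itertools.product([False, True], repeat=len(introns)):
        blocks: list[tuple[int, int]] = [tuple(tx.exons[0])]
        for k, intron in enumerate(introns):
            nxt = tx.exons[k + 1]
            if status[k]:
                s, _ = blocks[-1]
                blocks[-1] = (s, nxt[1])
            else:
                blocks.append(tuple(nxt))
        forms.append((status, blocks))
    return forms


def simulate_reads(
    truth: SyntheticTruth,
    sample: str,
    depth_factor: float = 1.0,
    seed: int | None = None,
) -> list[AlignmentRecord]:
    """Simulate single-end spliced alignments for one sample.

    Per gene, the fragment count is NB(depth_factor·µ_g, α_g); fragments are
    then allocated to retention forms with probability proportional to form
    abundance × start positions, and placed uniformly. Output is sorted by
    coordinate.
    """
    condition = truth.condition_of(sample)
    rng = _rng(truth.seed if seed is None else seed, "reads", sample)
    L = truth.config.read_length
    records: list[AlignmentRecord] = []
    for gene_id in sorted(truth.annotation.genes):
        gene = truth.annotation.genes[gene_id]
        gintrons = truth.introns_of_gene(gene_id)
        r = truth.retention.loc[[iv.intron_id for iv in gintrons], condition].to_numpy()
        mu = depth_factor * truth.gene_mu.loc[gene_id, condition]
        alpha = truth.gene_dispersion[gene_id]
        n_frag = int(rng.negative_binomial(1.0 / alpha, 1.0 / (1.0 + alpha * mu)))
        if n_frag == 0:
            continue
        forms = _transcript_forms(gene, gintrons)
        weights = []
        positions = []
        for status, blocks in forms:
            p_status = float(
                np.prod([r[k] if keep else 1 - r[k] for k, keep in enumerate(status)])
            )
            tlen = sum(e - s for s, e in blocks)
            npos = max(tlen - L + 1, 0)
            weights.append(p_status * npos)
            positions.append(npos)
        weights = np.asarray(weights, dtype=float)
        if weights.sum() <= 0:
            raise ValueError(f"gene {gene_id}: no form long enough for read length")
        counts = rng.multinomial(n_frag, weights / weights.sum())
        read_no = 0
        for (status, blocks), n_form, npos in zip(forms, counts, positions):
            if n_form == 0:
                continue
            retained_ids = tuple(
                gintrons[k].intron_id for k, keep in enumerate(status) if keep
            )
            starts = rng.integers(0, npos, size=n_form)
            for t0 in starts:
                rec_blocks = _slice_blocks(blocks, int(t0), L)
                records.append(
                    AlignmentRecord(
                        read_id=f"{sample}:{gene_id}:{read_no}",
                        sample=sample,
                        chrom=gene.chrom,
                        blocks=rec_blocks,
                        strand=gene.strand,
                        retained=retained_ids,
                    )
                )
                read_no += 1
    records.sort(key=lambda rec: (rec.chrom, rec.start, rec.end, rec.read_id))
    return records


def _slice_blocks(
    blocks: Sequence[tuple[int, int]], t0: int, length: int
) -> tuple[tuple[int, int], ...]:
    """Genomic blocks covered by a read at transcript offset ``t0``."""
    out: list[tuple[int, int]] = []
    remaining = length
    offset = t0
    for s, e in blocks:
        blen = e - s
        if offset >= blen:
            offset -= blen
            continue
        take = min(blen - offset, remaining)
        out.append((s + offset, s + offset + take))
        remaining -= take
        offset = 0
        if remaining == 0:
            break
    if remaining:
        raise ValueError("read extends past transcript end")
    return tuple(out)


def cpg_positions(genome: dict[str, str]) -> dict[str, np.ndarray]:
    """0-based positions of the C in every CpG dinucleotide, per chromosome."""
    return {
        chrom: np.array([m.start() for m in re.finditer("CG", seq.upper())], dtype=int)
        for chrom, seq in genome.items()
    }


def _dip_intervals(truth: SyntheticTruth, condition: str) -> list[tuple[str, int, int]]:
    ivs = []
    retained = set(truth.retained_intron_ids(condition))
    flank = truth.config.dip_flank
    for iv in truth.introns:
        if iv.intron_id in retained:
            ivs.append((iv.chrom, iv.start - flank, iv.end + flank))
    return ivs


def simulate_methylome(
    truth: SyntheticTruth,
    sample: str,
    mean_coverage: float | None = None,
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate a per-CpG methylation count table for one sample.

    Coverage is Poisson(mean_coverage); methylated counts are binomial with
    success probability m0, dipped to m0 − d inside retained introns and
    their ±flank around the splice sites for the sample's condition.
    Returns a DataFrame (chrom, pos, methylated, total).
    """
    cfg = truth.config
    cov = cfg.mean_coverage if mean_coverage is None else mean_coverage
    if cov <= 0:
        raise ValueError("mean_coverage must be > 0")
    rng = _rng(truth.seed if seed is None else seed, "meth", sample)
    condition = truth.condition_of(sample)
    dips = _dip_intervals(truth, condition)
    frames = []
    for chrom, pos in cpg_positions(truth.genome).items():
        m = np.full(pos.shape, cfg.m0)
        for dchrom, s, e in dips:
            if dchrom == chrom:
                m[(pos >= s) & (pos < e)] = cfg.m0 - cfg.dip_depth
        total = rng.poisson(cov, size=pos.shape)
        meth = rng.binomial(total, m)
        frames.append(
            pd.DataFrame(
                {"chrom": chrom, "pos": pos, "methylated": meth, "total": total}
            )
        )
    return pd.concat(frames, ignore_index=True)


def simulate_peaks(
    truth: SyntheticTruth,
    mark: str = "H3K4me1",
    condition: str = "diagnosis",
    seed: int | None = None,
) -> pd.DataFrame:
    """Simulate histone-mark peak intervals enriched near retained-intron
    splice sites.

    Peak midpoints follow a Poisson process with rate λ_near inside the
    ±window around each retained intron's splice sites and λ_bg elsewhere.
    Returns a BED-like DataFrame (chrom, start, end, name) sorted by
    coordinate.
    """
    cfg = truth.config
    rng = _rng(truth.seed if seed is None else seed, "peaks", mark, condition)
    retained = set(truth.retained_intron_ids(condition))
    windows: list[tuple[str, int, int]] = []
    for iv in truth.introns:
        if iv.intron_id in retained:
            for ss in iv.splice_sites():
                windows.append((iv.chrom, ss - cfg.peak_window, ss + cfg.peak_window))
    midpoints: list[tuple[str, int]] = []
    for chrom, s, e in windows:
        n = rng.poisson(cfg.lambda_near * (e - s))
        midpoints += [(chrom, int(p)) for p in rng.integers(s, e, size=n)]
    for chrom, seq in truth.genome.items():
        glen = len(seq)
        mask = np.zeros(glen, dtype=bool)
        for wchrom, s, e in windows:
            if wchrom == chrom:
                mask[max(0, s) : min(glen, e)] = True
        bg_len = int((~mask).sum())
        n_bg = rng.poisson(cfg.lambda_bg * bg_len)
        bg_pos = np.flatnonzero(~mask)
        if n_bg and len(bg_pos):
            picks = rng.choice(bg_pos, size=n_bg, replace=True)
            midpoints += [(chrom, int(p)) for p in picks]
    half = cfg.peak_width // 2
    rows = [
        {"chrom": chrom, "start": max(0, mid - half), "end": mid + half}
        for chrom, mid in midpoints
    ]
    peaks = pd.DataFrame(rows, columns=["chrom", "start", "end"])
    peaks = peaks.sort_values(["chrom", "start", "end"]).reset_index(drop=True)
    peaks["name"] = [f"{mark}_{i}" for i in range(len(peaks))]
    return peaks
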