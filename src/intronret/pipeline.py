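"""End-to-end pipeline orchestration.

Runs simulate (or load) → IR quantification → depth subsampling →
differential statistics (genes / introns / exons) → methylation →
chromatin → integration, writing every stage's tables as TSV plus a JSON
manifest of parameters, the seed, and SHA-256 hashes of all outputs. A rerun
with the same config is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import yaml
from intervaltree import IntervalTree

from . import io as irio
from .annotation import GenomeAnnotation, IntronUnit, build_feature_map, derive_intron_units, introns_to_bed, parse_annotation
from .chromatin import peak_counts_near_splice_sites, quartile_stratified_enrichment
from .integration import (
    compute_tpm,
    intron_feature_compare,
    inverse_relation_screen,
    ir_frequency_correlation,
)
from .irquant import IRThresholds, call_ir_events, measure_introns, subsample_alignments
from .methylation import DMRParams, call_dmrs, dmr_feature_density, profile_group_test, splice_anchor_profile
from .simulate import (
    AlignmentRecord,
    CohortConfig,
    SyntheticTruth,
    build_truth,
    simulate_methylome,
    simulate_peaks,
    simulate_reads,
    _hash32,
)

logger = logging.getLogger(__name__)

STAGES = (
    "simulate",
    "quantify",
    "subsample",
    "diff",
    "methylation",
    "chromatin",
    "integrate",
)


@dataclass
class RunConfig:
    """Validated run configuration (from a YAML mapping)."""

    seed: int
    output_dir: str
    simulate: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    dmr: dict = field(default_factory=dict)
    comparison: tuple[str, str] = ("diagnosis", "control")
    retained_ratio_threshold: float = 0.2
    window: int = 200
    promoter_span: int = 2000
    ir_thresh: float = 0.1
    fc_thresh: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "seed" not in raw:
            raise ValueError("config requires a seed")
        if "output_dir" not in raw:
            raise ValueError("config requires an output_dir")
        if "simulate" not in raw or not raw["simulate"].get("enabled", True):
            raise ValueError(
                "this build runs on a simulated cohort: provide a simulate block"
            )
        cfg = dict(raw)
        if "comparison" in cfg:
            cfg["comparison"] = tuple(cfg["comparison"])
        return cls(**cfg)

    def cohort_config(self) -> CohortConfig:
        params = {k: v for k, v in self.simulate.items() if k != "enabled"}
        if "n_samples" in params:
            params["n_samples"] = dict(params["n_samples"])
        if "mu_range" in params:
            params["mu_range"] = tuple(params["mu_range"])
        return CohortConfig(**params)

    def ir_thresholds(self) -> IRThresholds:
        return IRThresholds(**self.thresholds)

    def dmr_params(self) -> DMRParams:
        return DMRParams(**self.dmr)

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000003 + _hash32(stage)) % (2**31)


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages; returns the manifest (also written to disk)."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}, "outputs": {}}
    written: list[Path] = []

    def save_tsv(df: pd.DataFrame, name: str) -> Path:
        path = out / name
        df.to_csv(path, sep="\t", index=True if df.index.name else False, float_format="%.6g")
        written.append(path)
        return path

    try:
        # --- simulate -------------------------------------------------------
        cohort = config.cohort_config()
        truth = build_truth(cohort, seed=config.stage_seed("simulate"))
        irio.write_fasta(truth.genome, out / "genome.fa")
        irio.write_gtf(truth.annotation, out / "annotation.gtf")
        irio.write_sample_sheet(truth.sample_sheet, out / "sample_sheet.tsv")
        written += [out / "genome.fa", out / "annotation.gtf", out / "sample_sheet.tsv"]
        samples = list(truth.sample_sheet["sample"])
        conditions = dict(
            zip(truth.sample_sheet["sample"], truth.sample_sheet["condition"])
        )
        reads = {
            s: simulate_reads(truth, s, seed=config.stage_seed(f"reads:{s}"))
            for s in samples
        }
        for s in samples:
            irio.write_sam(reads[s], truth.annotation.chrom_lengths, out / f"{s}.sam")
            written.append(out / f"{s}.sam")
        meth_samples = [s for s in samples]
        tracks = {
            s: simulate_methylome(truth, s, seed=config.stage_seed(f"meth:{s}"))
            for s in meth_samples
        }
        for s in meth_samples:
            irio.write_methylation_tsv(tracks[s], out / f"{s}.meth.tsv")
            written.append(out / f"{s}.meth.tsv")
        peaks = simulate_peaks(truth, seed=config.stage_seed("peaks"))
        irio.write_bed(peaks, out / "peaks.bed")
        written.append(out / "peaks.bed")
        (out / "introns.bed").write_text(introns_to_bed(truth.introns))
        written.append(out / "introns.bed")
        manifest["stages"]["simulate"] = {
            "n_samples": len(samples),
            "n_genes": cohort.n_genes,
            "n_introns": len(truth.introns),
        }

        introns = truth.introns
        annotation = truth.annotation

        # --- quantify -------------------------------------------------------
        thresholds = config.ir_thresholds()
        ir_tables = {}
        for s in samples:
            ir_tables[s] = measure_introns(reads[s], introns, sample=s)
            save_tsv(ir_tables[s], f"{s}.ir.tsv")
        manifest["stages"]["quantify"] = {"thresholds": dataclasses.asdict(thresholds)}

        # --- subsample to uniform depth ------------------------------------
        target = min(len(r) for r in reads.values())
        sub_reads = {
            s: subsample_alignments(reads[s], target, seed=config.stage_seed(f"sub:{s}"))
            for s in samples
        }
        sub_tables = {
            s: measure_introns(sub_reads[s], introns, sample=s) for s in samples
        }
        summaries = pd.DataFrame(
            [
                call_ir_events(
                    sub_tables[s], thresholds, s, conditions[s], depth_used=target
                ).__dict__
                for s in samples
            ]
        )
        save_tsv(summaries, "ir_event_summary.tsv")
        manifest["stages"]["subsample"] = {"target_fragments": target}

        # --- count matrices and differential statistics --------------------
        gene_mat = feature_count_matrix(reads, annotation)
        exon_mat, exon_genes = exon_count_matrix(reads, annotation)
        intronic, junction = ir_count_matrices(ir_tables, introns)
        for mat, name, idx in (
            (gene_mat, "gene_counts.tsv", "gene_id"),
            (exon_mat, "exon_counts.tsv", "exon_id"),
            (intronic, "intronic_counts.tsv", "intron_id"),
            (junction, "junction_counts.tsv", "intron_id"),
        ):
            mat.index.name = idx
            save_tsv(mat, name)
        ga, gb = config.comparison
        use = [s for s in samples if conditions[s] == ga] + [
            s for s in samples if conditions[s] == gb
        ]
        groups = pd.Series([conditions[s] for s in use], index=use)
        from .stats import differential_exon_usage, differential_ir, nb_wald_test

        diff_genes = nb_wald_test(gene_mat[groups.index], groups)
        diff_introns = differential_ir(
            intronic[groups.index], junction[groups.index], groups
        )
        diff_exons = differential_exon_usage(
            exon_mat[groups.index], gene_mat[groups.index], exon_genes, groups
        )
        save_tsv(diff_genes, "diff_genes.tsv")
        save_tsv(diff_introns, "diff_introns.tsv")
        save_tsv(diff_exons, "diff_exons.tsv")
        manifest["stages"]["diff"] = {"comparison": [ga, gb]}

        # --- retained / non-retained intron split (measured, not truth) ----
        diag_samples = [s for s in samples if conditions[s] == ga]
        mean_ratio = (
            pd.concat([ir_tables[s] for s in diag_samples])
            .groupby("intron_id")["ir_ratio"]
            .mean()
        )
        retained_ids = set(mean_ratio.index[mean_ratio >= config.retained_ratio_threshold])
        retained = [iv for iv in introns if iv.intron_id in retained_ids]
        non_retained = [iv for iv in introns if iv.intron_id not in retained_ids]

        # --- methylation ----------------------------------------------------
        dmr_params = config.dmr_params()
        tracks_a = [tracks[s] for s in samples if conditions[s] == ga]
        tracks_b = [tracks[s] for s in samples if conditions[s] == gb]
        dmrs = call_dmrs(tracks_a, tracks_b, dmr_params)
        save_tsv(dmrs, "dmrs.tsv")
        fmap = build_feature_map(annotation, promoter_span=config.promoter_span)
        density = dmr_feature_density(dmrs, fmap)
        save_tsv(density, "dmr_feature_density.tsv")
        if retained and non_retained:
            profiles = splice_anchor_profile(
                tracks_a, retained, non_retained, window=config.window
            )
            save_tsv(profiles, "methylation_profiles.tsv")
            anchor_tests = profile_group_test(
                tracks_a, retained, non_retained, window=config.window
            )
            save_tsv(anchor_tests, "methylation_anchor_tests.tsv")
        manifest["stages"]["methylation"] = {
            "n_dmrs": int(len(dmrs)),
            "params": dataclasses.asdict(dmr_params),
        }

        # --- chromatin ------------------------------------------------------
        lengths = spliced_lengths(annotation)
        tpm = compute_tpm(gene_mat, lengths)
        counts_near = peak_counts_near_splice_sites(peaks, introns, window=config.window)
        save_tsv(counts_near, "peak_counts.tsv")
        diag_tpm = tpm[[s for s in samples if conditions[s] == ga]].mean(axis=1)
        labels = pd.Series(
            {iv.intron_id: iv.intron_id in retained_ids for iv in introns}
        )
        enrichment = quartile_stratified_enrichment(counts_near, diag_tpm, labels)
        save_tsv(enrichment, "peak_enrichment_by_quartile.tsv")
        manifest["stages"]["chromatin"] = {"n_peaks": int(len(peaks))}

        # --- integrate ------------------------------------------------------
        tpm.index.name = "gene_id"
        save_tsv(tpm, "tpm.tsv")
        intron_to_gene = pd.Series({iv.intron_id: iv.gene_id for iv in introns})
        hits = inverse_relation_screen(
            diff_introns, diff_genes, intron_to_gene,
            ir_thresh=config.ir_thresh, fc_thresh=config.fc_thresh,
        )
        save_tsv(hits, "inverse_relation_hits.tsv")
        corr = ir_frequency_correlation(tpm, summaries)
        save_tsv(corr, "ir_frequency_correlation.tsv")
        features = (
            intron_feature_compare(retained, non_retained)
            if retained and non_retained
            else {}
        )
        manifest["stages"]["integrate"] = {
            "n_inverse_hits": int(len(hits)),
            "intron_features": features,
        }
    except Exception as exc:
        (out / "FAILED").write_text(f"{type(exc).__name__}: {exc}\n")
        raise

    manifest["outputs"] = {
        p.name: hashlib.sha256(p.read_bytes()).hexdigest() for p in sorted(set(written))
    }
    manifest["config"] = _jsonable(dataclasses.asdict(config))
    manifest_path = out / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    return obj


def spliced_lengths(annotation: GenomeAnnotation) -> pd.Series:
    """Per-gene spliced transcript length (union of its first transcript's
    exons); the TPM effective length."""
    out = {}
    for gene_id, gene in annotation.genes.items():
        tx = next(iter(gene.transcripts.values()))
        out[gene_id] = sum(e - s for s, e in tx.exons)
    return pd.Series(out, dtype=float)


def _gene_trees(annotation: GenomeAnnotation) -> dict[str, IntervalTree]:
    trees: dict[str, IntervalTree] = {}
    for gene in annotation.genes.values():
        spans = [tx.span() for tx in gene.transcripts.values() if tx.exons]
        s = min(a for a, _ in spans)
        e = max(b for _, b in spans)
        trees.setdefault(gene.chrom, IntervalTree()).addi(s, e, gene.gene_id)
    return trees


def assign_gene(record: AlignmentRecord, trees: dict[str, IntervalTree]) -> str | None:
    """Gene whose span contains the read start (first match by gene id)."""
    tree = trees.get(record.chrom)
    if tree is None:
        return None
    hits = sorted(iv.data for iv in tree.at(record.start))
    return hits[0] if hits else None


def feature_count_matrix(
    reads: dict[str, Sequence[AlignmentRecord]], annotation: GenomeAnnotation
) -> pd.DataFrame:
    """Gene-level fragment count matrix (reads assigned by start position)."""
    trees = _gene_trees(annotation)
    gene_ids = sorted(annotation.genes)
    data = {}
    for sample, recs in reads.items():
        counts = dict.fromkeys(gene_ids, 0)
        for rec in recs:
            g = assign_gene(rec, trees)
            if g is not None:
                counts[g] += 1
        data[sample] = counts
    return pd.DataFrame(data, dtype=int).loc[gene_ids]


def exon_count_matrix(
    reads: dict[str, Sequence[AlignmentRecord]], annotation: GenomeAnnotation
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-exon fragment counts (a read counts for an exon when one of its
    aligned blocks overlaps it) and the exon→gene mapping."""
    exons: list[tuple[str, str, int, int]] = []  # exon_id, gene, start, end
    for gene_id in sorted(annotation.genes):
        gene = annotation.genes[gene_id]
        seen = set()
        for tx in gene.transcripts.values():
            for s, e in tx.exons:
                if (s, e) not in seen:
                    seen.add((s, e))
                    exons.append((f"{gene_id}:exon:{s}-{e}", gene_id, s, e))
    trees = _gene_trees(annotation)
    by_gene: dict[str, list[tuple[str, int, int]]] = {}
    for exon_id, gene_id, s, e in exons:
        by_gene.setdefault(gene_id, []).append((exon_id, s, e))
    exon_ids = [x[0] for x in exons]
    data = {}
    for sample, recs in reads.items():
        counts = dict.fromkeys(exon_ids, 0)
        for rec in recs:
            g = assign_gene(rec, trees)
            if g is None:
                continue
            for exon_id, s, e in by_gene.get(g, ()):
                if any(bs < e and be > s for bs, be in rec.blocks):
                    counts[exon_id] += 1
        data[sample] = counts
    mat = pd.DataFrame(data, dtype=int).loc[exon_ids]
    mapping = pd.Series({x[0]: x[1] for x in exons})
    return mat, mapping


def ir_count_matrices(
    ir_tables: dict[str, pd.DataFrame], introns: Sequence[IntronUnit]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rounded intronic-depth and junction count matrices (introns × samples)."""
    ids = [iv.intron_id for iv in introns]
    intronic = {}
    junction = {}
    for sample, table in ir_tables.items():
        t = table.set_index("intron_id")
        intronic[sample] = t["intronic_depth"].round().astype(int).reindex(ids)
        junction[sample] = t["junction_count"].astype(int).reindex(ids)
    return (
        pd.DataFrame(intronic).fillna(0).astype(int),
        pd.DataFrame(junction).fillna(0).astype(int),
    )
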