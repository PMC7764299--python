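"""Gene annotation model: GTF parsing, intron unit derivation, gene-feature maps.

All internal coordinates are 0-based half-open. GTF input/output is 1-based
inclusive; BED/bedGraph output is 0-based half-open.

An :class:`IntronUnit` is the unit of every intron-retention statistic
downstream: the gap between two adjacent exons of a transcript, annotated
with *exclusion zones* (sub-intervals covered by any exon of any transcript,
which must not contribute to intronic read depth) and sequence GC content.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
from gffutils.feature import feature_from_line
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

Interval = tuple[int, int]

# Feature-map labels, ordered by painting priority (higher value wins when a
# base is covered by several annotations).
FEATURE_LABELS = ("intergenic", "intron", "promoter", "three_utr", "five_utr", "exon")
_LABEL_CODE = {name: i for i, name in enumerate(FEATURE_LABELS)}


@dataclass
class Transcript:
    transcript_id: str
    exons: list[Interval] = field(default_factory=list)

    def span(self) -> Interval:
        return self.exons[0][0], self.exons[-1][1]


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    transcripts: dict[str, Transcript] = field(default_factory=dict)


@dataclass
class GenomeAnnotation:
    """Parsed annotation: genes/transcripts/exons plus chromosome lengths."""

    genes: dict[str, Gene]
    chrom_lengths: dict[str, int]
    # optional UTR intervals straight from the GTF, per label
    utrs: dict[str, list[tuple[str, int, int]]] = field(default_factory=dict)

    def exon_trees(self) -> dict[str, IntervalTree]:
        """Per-chromosome interval tree over the union of all exons."""
        trees: dict[str, IntervalTree] = {}
        for gene in self.genes.values():
            tree = trees.setdefault(gene.chrom, IntervalTree())
            for tx in gene.transcripts.values():
                for s, e in tx.exons:
                    tree.addi(s, e)
        for tree in trees.values():
            tree.merge_overlaps()
        return trees


@dataclass
class IntronUnit:
    """A measurable intron: coordinates, exclusion mask, GC content."""

    intron_id: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    exclusion_zones: list[Interval] = field(default_factory=list)
    measurable_length: int = 0
    gc_fraction: float = float("nan")

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError(f"intron {self.intron_id}: end <= start")

    @property
    def length(self) -> int:
        return self.end - self.start

    def splice_sites(self) -> tuple[int, int]:
        """(5'SS, 3'SS) genomic positions, strand-aware.

        On the + strand the 5' (donor) site is ``start``; on the − strand it
        is ``end`` (the higher coordinate).
        """
        if self.strand == "-":
            return self.end, self.start
        return self.start, self.end


class FeatureMap:
    """Per-base gene-feature labels for the whole genome.

    Every base carries exactly one label, resolved by the fixed priority
    exon > 5'UTR > 3'UTR > promoter > intron > intergenic.
    """

    def __init__(self, arrays: dict[str, np.ndarray]):
        self.arrays = arrays

    def label_at(self, chrom: str, pos: int) -> str:
        return FEATURE_LABELS[int(self.arrays[chrom][pos])]

    def total_bp(self) -> dict[str, int]:
        totals = dict.fromkeys(FEATURE_LABELS, 0)
        for arr in self.arrays.values():
            counts = np.bincount(arr, minlength=len(FEATURE_LABELS))
            for i, name in enumerate(FEATURE_LABELS):
                totals[name] += int(counts[i])
        return totals

    @property
    def genome_length(self) -> int:
        return sum(len(a) for a in self.arrays.values())


class AnnotationError(ValueError):
    pass


_UTR_TYPES = {
    "five_prime_utr": "five_utr",
    "5utr": "five_utr",
    "three_prime_utr": "three_utr",
    "3utr": "three_utr",
}


def parse_annotation(gtf_source, fasta_source) -> GenomeAnnotation:
    """Parse an Ensembl-dialect GTF against a genome sequence source.

    Parameters
    ----------
    gtf_source
        Path to a GTF file, or an iterable of GTF lines.
    fasta_source
        Mapping of chromosome name to sequence (``pyfaidx.Fasta`` or a plain
        dict of strings); defines the contigs and their lengths.

    Raises
    ------
    AnnotationError
        On a malformed line (reported with its line number) or a chromosome
        absent from the genome source.
    """
    chrom_lengths = {name: len(fasta_source[name]) for name in _contig_names(fasta_source)}
    genes: dict[str, Gene] = {}
    utrs: dict[str, list[tuple[str, int, int]]] = {"five_utr": [], "three_utr": []}

    if isinstance(gtf_source, (str, bytes)):
        with open(gtf_source) as fh:
            lines = fh.readlines()
    else:
        lines = list(gtf_source)

    for lineno, line in enumerate(lines, start=1):
        line = line.rstrip("\n")
        if not line or line.startswith("#"):
            continue
        if line.count("\t") != 8:
            raise AnnotationError(
                f"malformed GTF line {lineno}: expected 9 tab-separated fields"
            )
        try:
            feat = feature_from_line(line, dialect=None)
        except Exception as exc:
            raise AnnotationError(f"malformed GTF line {lineno}: {exc}") from exc
        ftype = feat.featuretype.lower()
        if ftype not in ("exon",) and ftype not in _UTR_TYPES:
            continue
        if feat.seqid not in chrom_lengths:
            raise AnnotationError(
                f"GTF line {lineno}: contig {feat.seqid!r} not present in genome source"
            )
        if feat.end < feat.start:
            raise AnnotationError(f"malformed GTF line {lineno}: end < start")
        start0, end0 = feat.start - 1, feat.end  # to 0-based half-open
        if start0 < 0 or end0 > chrom_lengths[feat.seqid]:
            raise AnnotationError(
                f"GTF line {lineno}: feature outside contig {feat.seqid} bounds"
            )
        if ftype in _UTR_TYPES:
            utrs[_UTR_TYPES[ftype]].append((feat.seqid, start0, end0))
            continue
        if feat.strand not in ("+", "-"):
            raise AnnotationError(f"GTF line {lineno}: strand must be + or -")
        try:
            gene_id = feat.attributes["gene_id"][0]
            tx_id = feat.attributes["transcript_id"][0]
        except KeyError as exc:
            raise AnnotationError(
                f"GTF line {lineno}: missing required attribute {exc}"
            ) from exc
        gene = genes.setdefault(gene_id, Gene(gene_id, feat.seqid, feat.strand))
        if gene.chrom != feat.seqid or gene.strand != feat.strand:
            raise AnnotationError(
                f"GTF line {lineno}: gene {gene_id} spans multiple contigs/strands"
            )
        tx = gene.transcripts.setdefault(tx_id, Transcript(tx_id))
        tx.exons.append((start0, end0))

    for gene in genes.values():
        for tx in gene.transcripts.values():
            tx.exons.sort()
            for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
                if s2 < e1:
                    raise AnnotationError(
                        f"transcript {tx.transcript_id}: overlapping exons "
                        f"[{s1},{e1}) and [{s2},{e2})"
                    )
    genes = {
        gid: g
        for gid, g in genes.items()
        if any(tx.exons for tx in g.transcripts.values())
    }
    return GenomeAnnotation(genes=genes, chrom_lengths=chrom_lengths, utrs=utrs)


def _contig_names(fasta_source) -> Iterable[str]:
    keys = getattr(fasta_source, "keys", None)
    if keys is not None:
        return list(keys())
    return list(fasta_source)


def _sequence(fasta_source, chrom: str, start: int, end: int) -> str:
    seq = fasta_source[chrom][start:end]
    return str(seq)


def gc_fraction(seq: str) -> float:
    if not seq:
        return float("nan")
    s = seq.upper()
    return (s.count("G") + s.count("C")) / len(s)


def derive_intron_units(
    annotation: GenomeAnnotation, genome=None
) -> list[IntronUnit]:
    """Derive one intron unit per gap between adjacent exons of a transcript.

    Introns are deduplicated by (chrom, start, end, strand) within each gene.
    Exclusion zones are computed against the union of all exons of all
    transcripts genome-wide; ``gc_fraction`` is computed on the full intron
    sequence when a genome source is given.
    """
    exon_trees = annotation.exon_trees()
    introns: list[IntronUnit] = []
    for gene_id in sorted(annotation.genes):
        gene = annotation.genes[gene_id]
        seen: set[tuple[str, int, int, str]] = set()
        for tx_id in sorted(gene.transcripts):
            tx = gene.transcripts[tx_id]
            for (s1, e1), (s2, e2) in zip(tx.exons, tx.exons[1:]):
                start, end = e1, s2
                if end == start:
                    logger.warning(
                        "zero-length intron at %s:%d (abutting exons in %s); skipped",
                        gene.chrom, start, tx_id,
                    )
                    continue
                key = (gene.chrom, start, end, gene.strand)
                if key in seen:
                    continue
                seen.add(key)
                zones = _overlap_zones(exon_trees.get(gene.chrom), start, end)
                excluded = sum(e - s for s, e in zones)
                gc = float("nan")
                if genome is not None:
                    gc = gc_fraction(_sequence(genome, gene.chrom, start, end))
                introns.append(
                    IntronUnit(
                        intron_id=f"{gene_id}:{gene.chrom}:{start}-{end}",
                        gene_id=gene_id,
                        chrom=gene.chrom,
                        start=start,
                        end=end,
                        strand=gene.strand,
                        exclusion_zones=zones,
                        measurable_length=(end - start) - excluded,
                        gc_fraction=gc,
                    )
                )
    return introns


def _overlap_zones(tree: IntervalTree | None, start: int, end: int) -> list[Interval]:
    if tree is None:
        return []
    zones = sorted(
        (max(iv.begin, start), min(iv.end, end)) for iv in tree.overlap(start, end)
    )
    merged: list[Interval] = []
    for s, e in zones:
        if merged and s <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], e))
        else:
            merged.append((s, e))
    return merged


def build_feature_map(
    annotation: GenomeAnnotation, promoter_span: int = 2000
) -> FeatureMap:
    """Assign every genomic base one feature label.

    The promoter is ``promoter_span`` bp upstream of each transcript start,
    strand-aware. Overlaps resolve by the fixed priority
    exon > 5'UTR > 3'UTR > promoter > intron > intergenic.
    """
    if promoter_span <= 0:
        raise ValueError("promoter_span must be > 0")
    arrays = {
        chrom: np.zeros(length, dtype=np.int8)
        for chrom, length in annotation.chrom_lengths.items()
    }

    def paint(chrom: str, s: int, e: int, label: str) -> None:
        arr = arrays[chrom]
        s, e = max(0, s), min(len(arr), e)
        if e > s:
            code = _LABEL_CODE[label]
            np.maximum(arr[s:e], code, out=arr[s:e])

    for gene in annotation.genes.values():
        for tx in gene.transcripts.values():
            if not tx.exons:
                continue
            span_s, span_e = tx.span()
            paint(gene.chrom, span_s, span_e, "intron")
            if gene.strand == "+":
                paint(gene.chrom, span_s - promoter_span, span_s, "promoter")
            else:
                paint(gene.chrom, span_e, span_e + promoter_span, "promoter")
    for label in ("three_utr", "five_utr"):
        for chrom, s, e in annotation.utrs.get(label, []):
            paint(chrom, s, e, label)
    for gene in annotation.genes.values():
        for tx in gene.transcripts.values():
            for s, e in tx.exons:
                paint(gene.chrom, s, e, "exon")
    return FeatureMap(arrays)


def introns_to_bed(introns: Sequence[IntronUnit]) -> str:
    """Render intron units as BED6 text (intron_id in the name column)."""
    lines = []
    for iv in sorted(introns, key=lambda i: (i.chrom, i.start, i.end)):
        lines.append(
            f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.intron_id}\t0\t{iv.strand}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
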