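"""Readers and writers for the standard formats the pipeline consumes.

SAM records go through pysam; FASTA through pyfaidx on read. GTF output is
1-based inclusive (Ensembl dialect); BED and bedGraph-style CpG tables are
0-based half-open. All tabular outputs are TSV with headers.
"""

from __future__ import annotations

import textwrap
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam

from .annotation import GenomeAnnotation
from .simulate import AlignmentRecord


def write_fasta(genome: dict[str, str], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for chrom in sorted(genome):
            fh.write(f">{chrom}\n")
            for line in textwrap.wrap(genome[chrom], width):
                fh.write(line + "\n")


def write_gtf(annotation: GenomeAnnotation, path: str | Path, source: str = "intronret") -> None:
    """Write exon features, 1-based inclusive, with gene_id/transcript_id."""
    lines = []
    for gene_id in sorted(annotation.genes):
        gene = annotation.genes[gene_id]
        for tx_id in sorted(gene.transcripts):
            tx = gene.transcripts[tx_id]
            for i, (s, e) in enumerate(tx.exons, start=1):
                attrs = (
                    f'gene_id "{gene_id}"; transcript_id "{tx_id}"; '
                    f'exon_number "{i}";'
                )
                lines.append(
                    f"{gene.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                    f"{gene.strand}\t.\t{attrs}"
                )
    Path(path).write_text("\n".join(lines) + "\n")


def _cigar(blocks: Sequence[tuple[int, int]]) -> list[tuple[int, int]]:
    ops = []
    for i, (s, e) in enumerate(blocks):
        if i:
            gap = s - blocks[i - 1][1]
            ops.append((3, gap))  # N
        ops.append((0, e - s))  # M
    return ops


def write_sam(
    records: Iterable[AlignmentRecord],
    chrom_lengths: dict[str, int],
    path: str | Path,
) -> None:
    """Write alignment records as a sorted SAM file with header."""
    chroms = sorted(chrom_lengths)
    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_lengths[c]} for c in chroms],
    }
    tid = {c: i for i, c in enumerate(chroms)}
    recs = sorted(records, key=lambda r: (tid[r.chrom], r.start, r.end, r.read_id))
    with pysam.AlignmentFile(str(path), "w", header=header) as out:
        for rec in recs:
            seg = pysam.AlignedSegment(out.header)
            seg.query_name = rec.read_id
            seg.reference_id = tid[rec.chrom]
            seg.reference_start = rec.start
            seg.cigartuples = _cigar(rec.blocks)
            seg.flag = 16 if rec.strand == "-" else 0
            seg.mapping_quality = 60
            length = sum(e - s for s, e in rec.blocks)
            seg.query_sequence = "N" * length
            out.write(seg)


def read_sam(path: str | Path, sample: str = "") -> list[AlignmentRecord]:
    """Read spliced alignments into block-based records (unmapped skipped)."""
    records = []
    with pysam.AlignmentFile(str(path), "r") as fh:
        for seg in fh:
            if seg.is_unmapped or seg.cigartuples is None:
                continue
            blocks = []
            pos = seg.reference_start
            for op, ln in seg.cigartuples:
                if op in (0, 7, 8):  # M / = / X
                    if blocks and blocks[-1][1] == pos:
                        blocks[-1] = (blocks[-1][0], pos + ln)
                    else:
                        blocks.append((pos, pos + ln))
                    pos += ln
                elif op in (2, 3):  # D / N both advance the reference
                    pos += ln
            records.append(
                AlignmentRecord(
                    read_id=seg.query_name,
                    sample=sample,
                    chrom=seg.reference_name,
                    blocks=tuple(blocks),
                    strand="-" if seg.is_reverse else "+",
                )
            )
    return records


def write_methylation_tsv(track: pd.DataFrame, path: str | Path) -> None:
    """bedGraph-style CpG table: chrom, start, end, methylated, total."""
    out = pd.DataFrame(
        {
            "chrom": track["chrom"],
            "start": track["pos"],
            "end": track["pos"] + 1,
            "methylated": track["methylated"],
            "total": track["total"],
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_methylation_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    return pd.DataFrame(
        {
            "chrom": df["chrom"],
            "pos": df["start"],
            "methylated": df["methylated"],
            "total": df["total"],
        }
    )


def write_bed(intervals: pd.DataFrame, path: str | Path) -> None:
    cols = [c for c in ("chrom", "start", "end", "name", "score", "strand") if c in intervals]
    intervals[cols].to_csv(path, sep="\t", index=False, header=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """Read BED3+ (extra columns beyond the first six ignored)."""
    names = ["chrom", "start", "end", "name", "score", "strand"]
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, : min(6, df.shape[1])]
    df.columns = names[: df.shape[1]]
    return df.sort_values(["chrom", "start", "end"]).reset_index(drop=True)


def write_sample_sheet(sheet: pd.DataFrame, path: str | Path) -> None:
    sheet.to_csv(path, sep="\t", index=False)


def read_sample_sheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t")
    if not {"sample", "condition"} <= set(sheet.columns):
        raise ValueError("sample sheet needs 'sample' and 'condition' columns")
    return sheet
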