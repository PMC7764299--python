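"""Shared fixtures: a small truth-known cohort and a hand-built toy locus."""

import numpy as np
import pytest

from intronret.annotation import GenomeAnnotation, Gene, Transcript, derive_intron_units
from intronret.simulate import AlignmentRecord, CohortConfig, build_truth


@pytest.fixture(scope="session")
def small_config():
    return CohortConfig(n_samples={"diagnosis": 4, "remission": 2, "control": 4})


@pytest.fixture(scope="session")
def small_truth(small_config):
    return build_truth(small_config, seed=11)


def make_gene(gene_id="G1", chrom="chr1", strand="+", exon_list=((0, 100), (200, 300))):
    gene = Gene(gene_id, chrom, strand)
    gene.transcripts[f"{gene_id}.t1"] = Transcript(
        f"{gene_id}.t1", [tuple(e) for e in exon_list]
    )
    return gene


@pytest.fixture
def toy_locus():
    """Gene with 4 exons / 3 introns on a 1 kb contig, plus its introns."""
    gene = make_gene(
        exon_list=((0, 100), (200, 300), (400, 500), (600, 700))
    )
    ann = GenomeAnnotation(genes={"G1": gene}, chrom_lengths={"chr1": 1000})
    introns = derive_intron_units(ann)
    return ann, introns


def read(blocks, read_id="r", sample="s"):
    return AlignmentRecord(
        read_id=read_id, sample=sample, chrom="chr1", blocks=tuple(blocks)
    )
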