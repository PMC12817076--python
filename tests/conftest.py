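import pytest

import annoteval as av

MINI_GFF = """\
##gff-version 3
chr1\ttest\tgene\t1\t500\t.\t+\t.\tID=g1
chr1\ttest\tmRNA\t1\t500\t.\t+\t.\tID=t1;Parent=g1
chr1\ttest\tCDS\t1\t500\t.\t+\t0\tParent=t1
"""

THREE_EXON_GFF = """\
##gff-version 3
chr1\ttest\tgene\t100\t600\t.\t+\t.\tID=g1
chr1\ttest\tmRNA\t100\t600\t.\t+\t.\tID=g1.t1;Parent=g1
chr1\ttest\tCDS\t100\t200\t.\t+\t0\tParent=g1.t1
chr1\ttest\tCDS\t300\t400\t.\t+\t0\tParent=g1.t1
chr1\ttest\tCDS\t500\t600\t.\t+\t0\tParent=g1.t1
"""

BUSCO_TABLE = """\
# BUSCO version is: 4.1.4
# Busco id\tStatus\tSequence\tScore\tLength
busco1\tComplete\tgeneA\t512.3\t300
busco2\tComplete\tgeneB\t410.0\t250
busco3\tDuplicated\tgeneC\t380.1\t200
busco4\tFragmented\tgeneD\t120.5\t90
busco5\tMissing
busco6\tComplete\tgeneE\t333.0\t270\textra\tcolumns
"""


@pytest.fixture
def mini_annotation():
    return av.parse_gff3(MINI_GFF)


@pytest.fixture
def three_exon_annotation():
    return av.parse_gff3(THREE_EXON_GFF)


@pytest.fixture
def busco_table_text():
    return BUSCO_TABLE


def make_gene(gid, exons, strand="+", contig="chr1", tid=None):
    """Single-transcript gene from a list of (start, end) exon coordinates."""
    segs = [av.CdsSegment(av.GenomicInterval(contig, s, e, strand))
            for s, e in exons]
    return av.GeneModel(gid, [av.TranscriptModel(tid or f"{gid}.t1", gid, segs)])


def make_set(genes, label=""):
    return av.AnnotationSet(genes, source_label=label)


@pytest.fixture
def synthetic_pair():
    """A 120-gene reference with a mixed bag of injected defects."""
    params = av.GenomeParams(n_genes=120, contig_length=1_000_000, seed=7,
                             isoform_probability=0.25)
    ref = av.generate_reference(params)
    spec = av.PerturbationSpec(inexact=20, missing=10, merged=10,
                               fragmented=10, seed=8,
                               spurious_transcript_rate=0.2)
    pred, truth = av.inject_defects(ref, spec)
    return ref, pred, truth
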