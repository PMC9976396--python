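import numpy as np
import pysam
import pytest

from msiscreen.regions import MsLocus, PipelineConfig


def make_panel(n, chrom="chr1", tract=15, spacing=500, start0=1000):
    """n equally spaced microsatellite loci with identical tract length."""
    return [
        MsLocus(f"L{i:02d}", chrom, start0 + spacing * i, start0 + spacing * i + tract)
        for i in range(n)
    ]


@pytest.fixture
def config():
    return PipelineConfig()


@pytest.fixture
def locus():
    return MsLocus("BAT_test", "chr1", 1000, 1015)


@pytest.fixture
def header():
    return pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6"}, "SQ": [{"SN": "chr1", "LN": 100_000}]}
    )


def make_read(header, start, cigar, mapq=60, flag=0, name="r", chrom="chr1"):
    """In-memory aligned record with sequence length derived from the CIGAR."""
    read = pysam.AlignedSegment(header)
    read.query_name = name
    read.reference_name = chrom
    read.reference_start = start
    read.mapping_quality = mapq
    read.flag = flag
    read.cigartuples = cigar
    qlen = sum(n for op, n in cigar if op in (0, 1, 4, 7, 8))
    read.query_sequence = "A" * qlen
    return read


def spanning_cigar(locus, flank=5, pad=2):
    """Pure-match CIGAR fully covering the flanked locus."""
    span = (locus.end + flank + pad) - (locus.start - flank - pad)
    return locus.start - flank - pad, [(0, span)]
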