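"""Per-locus indel-length distributions and normalized feature vectors.

A sample's evidence at one microsatellite locus is the histogram of tract
lengths observed across reads (the indel length distribution). Reads must
be primary, non-duplicate, MAPQ >= ``min_mapq``, and span the tract plus
``flank_bases`` on both sides. The observed length of a read is the
reference tract length adjusted by the net indel length *inside* the
tract, obtained by walking the CIGAR; indels in the flanks do not count.

Distributions are cleaned (lengths with count <= ``singleton_cutoff``
removed), max-normalized (each count divided by the largest count, so the
modal length maps to 1.0), and embedded in a fixed-width vector of
2*window+1 values indexed by length offset from the reference tract
length. A locus is evaluable when its post-cleaning depth reaches
``min_depth``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from .regions import MsLocus, PipelineConfig

logger = logging.getLogger(__name__)

__all__ = [
    "LengthDistribution",
    "FeatureVector",
    "read_passes_filters",
    "observed_length",
    "build_distribution",
    "clean_distribution",
    "normalize",
    "vectorize",
    "features_from_distribution",
    "extract_distributions",
    "extract_sample",
    "write_audit_tsv",
]

# CIGAR operation codes (SAM spec)
_CONSUMES_REF_QUERY = (0, 7, 8)  # M, =, X
_INSERTION = 1
_DELETION = 2
_REF_SKIP = 3


@dataclass
class LengthDistribution:
    """Histogram of observed tract lengths at one locus for one sample."""

    locus_name: str
    counts: dict[int, int]

    def __post_init__(self) -> None:
        for length, count in self.counts.items():
            if count < 1:
                raise ValueError(
                    f"{self.locus_name}: count {count} at length {length} must be >= 1"
                )
            if length < 0:
                raise ValueError(f"{self.locus_name}: negative length {length}")

    @property
    def depth(self) -> int:
        return sum(self.counts.values())


@dataclass(eq=False)
class FeatureVector:
    """Fixed-width, max-normalized depth profile over length offsets.

    ``values[i]`` is the normalized depth at length offset ``i - window``
    relative to the locus reference length; ``None`` when the locus is not
    evaluable (post-cleaning depth below the minimum).
    """

    locus_name: str
    values: Optional[np.ndarray]
    evaluable: bool
    depth: int


def read_passes_filters(
    read: pysam.AlignedSegment, locus: MsLocus, config: PipelineConfig
) -> bool:
    """Read-level filter: primary, non-duplicate, MAPQ, full flanked span."""
    if read.is_unmapped or read.is_duplicate or read.is_secondary or read.is_supplementary:
        return False
    if read.mapping_quality < config.min_mapq:
        return False
    lo, hi = locus.flanked_interval(config.flank_bases)
    # aligned span must cover [lo, hi) entirely; soft/hard clips shrink it
    return read.reference_start <= lo and read.reference_end is not None and read.reference_end >= hi


def observed_length(read: pysam.AlignedSegment, locus: MsLocus) -> int:
    """Tract length seen in one read: ref_length + insertions − deletions inside the tract.

    Walks the CIGAR tracking the reference coordinate. Deletions (and
    reference skips) contribute their overlap with [start, end); an
    insertion counts iff its reference position p satisfies
    start <= p < end (so an insertion at the exact left boundary is
    inside, at the right boundary outside). Matches/mismatches contribute
    reference span only.
    """
    cigar = read.cigartuples
    if cigar is None:
        raise ValueError(f"read {read.query_name}: no CIGAR")
    length = locus.ref_length
    ref = read.reference_start
    for op, n in cigar:
        if op in _CONSUMES_REF_QUERY:
            ref += n
        elif op in (_DELETION, _REF_SKIP):
            overlap = min(ref + n, locus.end) - max(ref, locus.start)
            if overlap > 0:
                length -= overlap
            ref += n
        elif op == _INSERTION:
            if locus.start <= ref < locus.end:
                length += n
        # S/H/P consume no reference
    if ref < locus.end:
        raise RuntimeError(
            f"read {read.query_name}: alignment ends before locus {locus.name}"
        )
    return length


def build_distribution(observed: list[int], locus: MsLocus) -> LengthDistribution:
    """Count observed lengths into a distribution."""
    counts: dict[int, int] = {}
    for length in observed:
        counts[length] = counts.get(length, 0) + 1
    return LengthDistribution(locus.name, dict(sorted(counts.items())))


def clean_distribution(
    dist: LengthDistribution, config: PipelineConfig
) -> LengthDistribution:
    """Drop lengths supported by <= ``singleton_cutoff`` reads (input unmodified)."""
    kept = {
        length: count
        for length, count in dist.counts.items()
        if count > config.singleton_cutoff
    }
    return LengthDistribution(dist.locus_name, kept)


def normalize(dist: LengthDistribution) -> dict[int, float]:
    """Divide each count by the maximum count; the mode maps to exactly 1.0."""
    if not dist.counts:
        raise ValueError(f"{dist.locus_name}: nothing to normalize")
    peak = max(dist.counts.values())
    return {length: count / peak for length, count in dist.counts.items()}


def vectorize(
    normalized: dict[int, float],
    locus: MsLocus,
    config: PipelineConfig,
    depth: int,
) -> FeatureVector:
    """Embed a normalized profile into a fixed-width offset-indexed vector.

    Index ``offset + window`` holds the value at length
    ``ref_length + offset``; absent lengths are 0.0, lengths outside the
    window are dropped with a warning. ``evaluable`` records whether the
    depth filter passed.
    """
    w = config.window
    values = np.zeros(2 * w + 1, dtype=float)
    for length, value in normalized.items():
        offset = length - locus.ref_length
        if -w <= offset <= w:
            values[offset + w] = value
        else:
            logger.warning(
                "%s: length %d (offset %+d) outside window %d, dropped",
                locus.name, length, offset, w,
            )
    evaluable = depth >= config.min_depth
    if not evaluable:
        return FeatureVector(locus.name, None, False, depth)
    return FeatureVector(locus.name, values, True, depth)


def features_from_distribution(
    dist: LengthDistribution, locus: MsLocus, config: PipelineConfig
) -> FeatureVector:
    """Clean, normalize and vectorize one raw distribution."""
    cleaned = clean_distribution(dist, config)
    if cleaned.depth == 0:
        return FeatureVector(locus.name, None, False, 0)
    return vectorize(normalize(cleaned), locus, config, cleaned.depth)


def extract_distributions(
    bam_path: str | Path, panel: list[MsLocus], config: PipelineConfig
) -> dict[str, LengthDistribution]:
    """Raw (uncleaned) per-locus length distributions from an indexed BAM."""
    out: dict[str, LengthDistribution] = {}
    with pysam.AlignmentFile(str(bam_path), "rb") as bam:
        references = set(bam.references)
        for locus in panel:
            if locus.chrom not in references:
                logger.warning(
                    "%s: chromosome %s absent from %s header; locus not evaluable",
                    locus.name, locus.chrom, bam_path,
                )
                out[locus.name] = LengthDistribution(locus.name, {})
                continue
            lo, hi = locus.flanked_interval(config.flank_bases)
            lengths = [
                observed_length(read, locus)
                for read in bam.fetch(locus.chrom, lo, hi)
                if read_passes_filters(read, locus, config)
            ]
            out[locus.name] = build_distribution(lengths, locus)
    return out


def extract_sample(
    bam_path: str | Path, panel: list[MsLocus], config: PipelineConfig
) -> dict[str, FeatureVector]:
    """Full per-sample extraction: fetch, filter, count, clean, normalize, vectorize."""
    dists = extract_distributions(bam_path, panel, config)
    by_name = {locus.name: locus for locus in panel}
    return {
        name: features_from_distribution(dist, by_name[name], config)
        for name, dist in dists.items()
    }


def write_audit_tsv(
    dists: dict[str, LengthDistribution],
    config: PipelineConfig,
    path: str | Path,
) -> None:
    """Per-sample audit table: locus, length, raw count, normalized value."""
    with open(path, "w") as fh:
        fh.write("locus\tlength\traw_count\tnormalized\n")
        for name, dist in dists.items():
            cleaned = clean_distribution(dist, config)
            norm = normalize(cleaned) if cleaned.counts else {}
            for length in sorted(dist.counts):
                fh.write(
                    f"{name}\t{length}\t{dist.counts[length]}\t"
                    f"{norm.get(length, 0.0):.6g}\n"
                )
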