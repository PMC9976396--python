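"""Synthetic microsatellite read data with known truth.

The generator emulates the two processes that shape an indel-length
distribution at a microsatellite locus in targeted sequencing of a
tumor sample:

* **Stutter** - polymerase slippage during PCR/sequencing puts a
  fraction ``stutter_p`` of reads at the wrong tract length; slip
  magnitudes follow a geometric law (``stutter_decay``) and are
  contractions with probability ``deletion_bias`` (left-shifted minor
  peaks, as seen in real MSI electropherograms and read data).
* **Instability** - at an unstable locus of a mismatch-repair-deficient
  sample, a ``purity`` fraction of reads (the tumor-derived fraction)
  centres on a contracted allele ``msi_shift`` bases below the reference
  tract length, with the same stutter on top; the remaining reads come
  from admixed normal cells and follow the stable process.

Read depth per locus is Poisson(``depth_mean``). A dMMR sample shifts a
random ``unstable_locus_fraction`` subset of panel loci; a pMMR sample
shifts none. Samples can optionally be written as sorted, indexed BAM
files whose CIGARs encode the simulated indels, with configurable decoy
reads that violate each read filter.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import pysam

from .features import LengthDistribution, features_from_distribution
from .regions import MsLocus, PipelineConfig
from .training import STABLE_LABEL, UNSTABLE_LABEL, LabeledSample

__all__ = [
    "SimulationParams",
    "SyntheticSample",
    "simulate_locus",
    "simulate_cohort",
    "to_labeled_samples",
    "write_bam_fixture",
    "write_cohort_tsv",
]


@dataclass(frozen=True)
class SimulationParams:
    stutter_p: float = 0.05
    stutter_decay: float = 0.5
    deletion_bias: float = 0.8
    msi_shift: int = 6
    purity: float = 0.5
    unstable_locus_fraction: float = 0.8
    depth_mean: int = 200

    def __post_init__(self) -> None:
        for key in ("stutter_p", "stutter_decay", "deletion_bias",
                    "purity", "unstable_locus_fraction"):
            v = getattr(self, key)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{key}={v} outside [0, 1]")
        if self.msi_shift < 1:
            raise ValueError("msi_shift must be >= 1")
        if self.depth_mean < 1:
            raise ValueError("depth_mean must be >= 1")


@dataclass
class SyntheticSample:
    """Simulated sample: distributions per locus plus the generating truth."""

    sample_id: str
    truth_label: str  # pMMR | dMMR - recorded independently of any scorer
    distributions: dict[str, LengthDistribution]
    shifted_loci: frozenset[str]


def _stutter_offsets(n: int, params: SimulationParams, rng: np.random.Generator) -> np.ndarray:
    """Signed slippage offsets: 0 w.p. 1-stutter_p, else geometric magnitude
    with contraction probability ``deletion_bias``."""
    offsets = np.zeros(n, dtype=int)
    slipped = rng.random(n) < params.stutter_p
    k = int(slipped.sum())
    if k:
        mag = rng.geometric(1.0 - params.stutter_decay, size=k)
        sign = np.where(rng.random(k) < params.deletion_bias, -1, 1)
        offsets[slipped] = sign * mag
    return offsets


def simulate_locus(
    locus: MsLocus,
    unstable: bool,
    params: SimulationParams,
    rng: np.random.Generator,
) -> LengthDistribution:
    """One locus's length distribution under the stutter/instability mixture."""
    depth = int(rng.poisson(params.depth_mean))
    if depth == 0:
        return LengthDistribution(locus.name, {})
    base = np.full(depth, locus.ref_length, dtype=int)
    if unstable:
        tumor = rng.random(depth) < params.purity
        base[tumor] -= params.msi_shift
    lengths = np.maximum(base + _stutter_offsets(depth, params, rng), 0)
    counts = Counter(int(v) for v in lengths)
    return LengthDistribution(locus.name, dict(sorted(counts.items())))


def simulate_cohort(
    panel: list[MsLocus],
    n_stable: int,
    n_unstable: int,
    params: SimulationParams,
    seed: int,
) -> list[SyntheticSample]:
    """Reproducible cohort: ``n_stable`` pMMR then ``n_unstable`` dMMR samples.

    Sample ids are neutral (``S0001`` ...) so nothing downstream can read
    the truth off the identifier.
    """
    if n_stable + n_unstable < 1:
        raise ValueError("cohort must contain at least one sample")
    rng = np.random.default_rng(seed)
    n_shift = max(1, round(params.unstable_locus_fraction * len(panel)))
    samples: list[SyntheticSample] = []
    truths = [STABLE_LABEL] * n_stable + [UNSTABLE_LABEL] * n_unstable
    for i, truth in enumerate(truths, start=1):
        if truth == UNSTABLE_LABEL:
            picked = rng.choice(len(panel), size=n_shift, replace=False)
            shifted = frozenset(panel[j].name for j in picked)
        else:
            shifted = frozenset()
        dists = {
            locus.name: simulate_locus(locus, locus.name in shifted, params, rng)
            for locus in panel
        }
        samples.append(SyntheticSample(f"S{i:04d}", truth, dists, shifted))
    return samples


def to_labeled_samples(
    cohort: list[SyntheticSample], panel: list[MsLocus], config: PipelineConfig
) -> list[LabeledSample]:
    """Featurize a synthetic cohort for training/scoring (truth becomes the label)."""
    by_name = {locus.name: locus for locus in panel}
    out = []
    for s in cohort:
        features = {
            name: features_from_distribution(dist, by_name[name], config)
            for name, dist in s.distributions.items()
        }
        out.append(LabeledSample(s.sample_id, s.truth_label, features))
    return out


@dataclass(frozen=True)
class DecoySpec:
    """Per-locus counts of reads violating one filter each (for filter tests)."""

    n_duplicate: int = 0
    n_low_mapq: int = 0
    n_partial_overlap: int = 0


def _make_read(
    header: pysam.AlignmentHeader,
    name: str,
    chrom: str,
    locus: MsLocus,
    observed: int,
    flank: int,
    pad: int = 2,
    mapq: int = 60,
    flag: int = 0,
    left_truncate: int = 0,
) -> pysam.AlignedSegment:
    """One mapped record spanning the flanked locus with the indel encoded in CIGAR."""
    ref_start = locus.start - flank - pad + left_truncate
    ref_end = locus.end + flank + pad
    delta = observed - locus.ref_length
    if delta == 0:
        cigar = [(0, ref_end - ref_start)]
    elif delta < 0:
        d = -delta
        if d > locus.ref_length:
            raise ValueError(f"cannot delete {d} bases from {locus.ref_length} bp tract")
        # deletion starts at the tract start, wholly inside [start, end)
        cigar = [(0, locus.start - ref_start), (2, d), (0, ref_end - locus.start - d)]
    else:
        # insertion at the tract start boundary (counts as inside)
        cigar = [(0, locus.start - ref_start), (1, delta), (0, ref_end - locus.start)]
    qlen = sum(n for op, n in cigar if op in (0, 1, 4, 7, 8))
    read = pysam.AlignedSegment(header)
    read.query_name = name
    read.reference_name = chrom
    read.reference_start = ref_start
    read.mapping_quality = mapq
    read.flag = flag
    read.cigartuples = cigar
    read.query_sequence = "A" * qlen
    read.query_qualities = pysam.qualitystring_to_array("I" * qlen)
    return read


def write_bam_fixture(
    sample: SyntheticSample,
    panel: list[MsLocus],
    out_path: str | Path,
    flank: int = 5,
    decoys: Optional[DecoySpec] = None,
) -> Path:
    """Write the sample's reads as a coordinate-sorted, indexed BAM.

    Every simulated read becomes one primary MAPQ-60 record spanning the
    flanked locus. Decoy reads, when requested, each violate exactly one
    read filter (duplicate flag, MAPQ 19, or missing the left flank) and
    must be excluded by extraction.
    """
    out_path = Path(out_path)
    decoys = decoys or DecoySpec()
    chrom_len: dict[str, int] = {}
    for locus in panel:
        chrom_len[locus.chrom] = max(
            chrom_len.get(locus.chrom, 0), locus.end + flank + 100
        )
    chroms = sorted(chrom_len)
    header = pysam.AlignmentHeader.from_dict({
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": chrom_len[c]} for c in chroms],
    })
    reads: list[pysam.AlignedSegment] = []
    serial = 0
    for locus in panel:
        dist = sample.distributions.get(locus.name)
        if dist is None:
            continue
        for length in sorted(dist.counts):
            for _ in range(dist.counts[length]):
                serial += 1
                reads.append(_make_read(
                    header, f"r{serial:06d}", locus.chrom, locus, length, flank
                ))
        ref = locus.ref_length
        for _ in range(decoys.n_duplicate):
            serial += 1
            reads.append(_make_read(
                header, f"d{serial:06d}", locus.chrom, locus, ref, flank, flag=0x400
            ))
        for _ in range(decoys.n_low_mapq):
            serial += 1
            reads.append(_make_read(
                header, f"q{serial:06d}", locus.chrom, locus, ref, flank, mapq=19
            ))
        for _ in range(decoys.n_partial_overlap):
            serial += 1
            # starts one base into the flank: fails the full-span requirement
            reads.append(_make_read(
                header, f"p{serial:06d}", locus.chrom, locus, ref, flank,
                left_truncate=3,
            ))
    order = {c: i for i, c in enumerate(chroms)}
    reads.sort(key=lambda r: (order[r.reference_name], r.reference_start))
    with pysam.AlignmentFile(str(out_path), "wb", header=header) as bam:
        for read in reads:
            bam.write(read)
    pysam.index(str(out_path))
    return out_path


def write_cohort_tsv(cohort: list[SyntheticSample], out_dir: str | Path) -> None:
    """Distribution and truth tables for a simulated cohort."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    with open(out_dir / "distributions.tsv", "w") as fh:
        fh.write("sample_id\tlocus\tlength\tcount\n")
        for s in cohort:
            for name, dist in s.distributions.items():
                for length in sorted(dist.counts):
                    fh.write(f"{s.sample_id}\t{name}\t{length}\t{dist.counts[length]}\n")
    with open(out_dir / "truth.tsv", "w") as fh:
        fh.write("sample_id\tlabel\n")
        for s in cohort:
            fh.write(f"{s.sample_id}\t{s.truth_label}\n")
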