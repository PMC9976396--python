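import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from msiscreen.features import (
    LengthDistribution,
    build_distribution,
    clean_distribution,
    features_from_distribution,
    normalize,
    read_passes_filters,
    vectorize,
    observed_length,
)
from msiscreen.regions import MsLocus, PipelineConfig

from conftest import make_read, spanning_cigar

M, I, D, N, S, H = 0, 1, 2, 3, 4, 5


def walk_oracle(cigar, ref_start, locus):
    """Brute-force per-base alignment walk: count inserted/deleted bases in the tract."""
    ins = dele = 0
    ref = ref_start
    for op, n in cigar:
        for _ in range(n):
            if op in (0, 7, 8):
                ref += 1
            elif op in (2, 3):
                if locus.start <= ref < locus.end:
                    dele += 1
                ref += 1
            elif op == 1:
                if locus.start <= ref < locus.end:
                    ins += 1
    return locus.ref_length + ins - dele


class TestReadFilters:
    def test_clean_read_passes(self, header, locus, config):
        start, cigar = spanning_cigar(locus)
        assert read_passes_filters(make_read(header, start, cigar), locus, config)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"mapq": 19},            # below MAPQ threshold
            {"flag": 0x400},         # duplicate
            {"flag": 0x100},         # secondary
            {"flag": 0x800},         # supplementary
            {"flag": 0x4},           # unmapped
        ],
    )
    def test_single_violation_excludes(self, header, locus, config, kwargs):
        start, cigar = spanning_cigar(locus)
        assert not read_passes_filters(make_read(header, start, cigar, **kwargs), locus, config)

    def test_mapq_boundary_inclusive(self, header, locus, config):
        start, cigar = spanning_cigar(locus)
        assert read_passes_filters(make_read(header, start, cigar, mapq=20), locus, config)

    def test_duplicate_high_mapq_still_excluded(self, header, locus, config):
        start, cigar = spanning_cigar(locus)
        assert not read_passes_filters(
            make_read(header, start, cigar, mapq=60, flag=0x400), locus, config
        )

    def test_partial_flank_overlap_excluded(self, header, locus, config):
        # starts one base into the left flank: not a complete flanked span
        start = locus.start - config.flank_bases + 1
        span = locus.end + config.flank_bases - start
        assert not read_passes_filters(
            make_read(header, start, [(M, span)]), locus, config
        )

    def test_exact_flanked_span_passes(self, header, locus, config):
        start = locus.start - config.flank_bases
        span = locus.end + config.flank_bases - start
        assert read_passes_filters(make_read(header, start, [(M, span)]), locus, config)

    def test_soft_clip_shrinking_span_excluded(self, header, locus, config):
        # clipped bases do not align, so the flanked interval is not covered
        start = locus.start - config.flank_bases + 2
        span = locus.end + config.flank_bases - start
        assert not read_passes_filters(
            make_read(header, start, [(S, 10), (M, span)]), locus, config
        )

    def test_filter_monotonicity(self, header, locus):
        """Raising min_mapq or flank_bases never admits more reads."""
        rng = np.random.default_rng(7)
        reads = []
        for i in range(60):
            start = int(rng.integers(locus.start - 12, locus.start - 2))
            end = int(rng.integers(locus.end + 2, locus.end + 12))
            reads.append(make_read(header, start, [(M, end - start)],
                                   mapq=int(rng.integers(0, 61)), name=f"r{i}"))
        def n_pass(mapq, flank):
            cfg = PipelineConfig(min_mapq=mapq, flank_bases=flank)
            return sum(read_passes_filters(r, locus, cfg) for r in reads)
        for mapq in (0, 10, 20, 40, 60):
            assert n_pass(mapq, 5) >= n_pass(mapq + 1, 5)
            for flank in (0, 2, 5, 8):
                assert n_pass(mapq, flank) >= n_pass(mapq, flank + 1)


# 20+ hand-written CIGAR cases over a 15 bp tract at [1000, 1015);
# each tuple: (ref_start, cigar, expected observed length or None -> oracle only)
CIGAR_CASES = [
    (990, [(M, 35)], 15),                                  # pure match
    (990, [(M, 13), (D, 2), (M, 20)], 13),                 # 2 bp del wholly inside
    (990, [(M, 15), (I, 3), (M, 20), (D, 1), (M, 5)], 18), # ins inside, del outside
    (990, [(M, 8), (D, 5), (M, 22)], 12),                  # del straddling left boundary
    (990, [(M, 23), (D, 5), (M, 12)], 13),                 # del straddling right boundary
    (990, [(M, 10), (D, 15), (M, 10)], 0),                 # del of entire tract
    (990, [(M, 10), (I, 1), (M, 25)], 16),                 # ins at left boundary: inside
    (990, [(M, 25), (I, 4), (M, 10)], 15),                 # ins at right boundary: outside
    (990, [(M, 5), (I, 2), (M, 30)], 15),                  # ins in left flank
    (990, [(M, 24), (I, 2), (M, 11)], 17),                 # ins at last tract base
    (990, [(M, 10), (D, 1), (M, 24)], 14),                 # 1 bp del at tract start
    (990, [(M, 24), (D, 1), (M, 10)], 14),                 # 1 bp del at last tract base
    (990, [(M, 12), (D, 2), (M, 4), (I, 3), (M, 17)], 16), # mixed del+ins inside
    (990, [(S, 6), (M, 35)], 15),                          # leading soft clip, full span
    (990, [(H, 4), (M, 35)], 15),                          # leading hard clip
    (990, [(M, 13), (N, 4), (M, 18)], 11),                 # ref skip treated as deletion
    (990, [(M, 2), (D, 3), (M, 30)], 15),                  # del confined to left flank
    (990, [(M, 28), (D, 3), (M, 4)], 15),                  # del confined to right flank
    (985, [(M, 15), (I, 5), (M, 25)], 20),                 # 5 bp expansion mid-tract
    (990, [(M, 13), (D, 4), (I, 2), (M, 18)], 13),         # adjacent del then ins
    (990, [(M, 11), (I, 2), (M, 2), (D, 2), (M, 20)], 15), # balancing ins/del inside
    (995, [(M, 18), (D, 2), (M, 12), (I, 1), (M, 3)], 13), # del inside, ins in flank
]


class TestObservedLength:
    @pytest.mark.parametrize("ref_start,cigar,expected", CIGAR_CASES)
    def test_matches_per_base_walk_oracle(self, header, locus, ref_start, cigar, expected):
        read = make_read(header, ref_start, cigar)
        got = observed_length(read, locus)
        assert got == walk_oracle(cigar, ref_start, locus)
        if expected is not None:
            assert got == expected

    def test_random_cigars_match_oracle(self, header, locus):
        rng = np.random.default_rng(11)
        for i in range(200):
            ref_start = int(rng.integers(985, 995))
            cigar = []
            ref = ref_start
            # random alternation of M with occasional I/D until past the locus
            while ref < locus.end + 8:
                cigar.append((M, int(rng.integers(1, 8))))
                ref += cigar[-1][1]
                op = rng.choice([M, I, D, None], p=[0.2, 0.3, 0.3, 0.2])
                if op == I:
                    cigar.append((I, int(rng.integers(1, 4))))
                elif op == D:
                    n = int(rng.integers(1, 4))
                    cigar.append((D, n))
                    ref += n
            read = make_read(header, ref_start, cigar, name=f"r{i}")
            assert observed_length(read, locus) == walk_oracle(cigar, ref_start, locus)


class TestDistributionPipeline:
    def test_counting(self, locus):
        dist = build_distribution([15, 15, 14, 15], locus)
        assert dist.counts == {14: 1, 15: 3}
        assert dist.depth == 4

    def test_empty(self, locus):
        dist = build_distribution([], locus)
        assert dist.counts == {} and dist.depth == 0

    def test_degenerate(self, locus):
        dist = build_distribution([15] * 30, locus)
        assert dist.counts == {15: 30} and dist.depth == 30

    def test_singleton_cleaning(self, locus, config):
        dist = LengthDistribution(locus.name, {15: 30, 13: 1})
        cleaned = clean_distribution(dist, config)
        assert cleaned.counts == {15: 30} and cleaned.depth == 30
        assert dist.counts == {15: 30, 13: 1}  # input unmodified

    def test_cleaning_keeps_pairs_and_empties_all_singletons(self, locus, config):
        assert clean_distribution(
            LengthDistribution(locus.name, {15: 2, 14: 2}), config
        ).counts == {15: 2, 14: 2}
        assert clean_distribution(
            LengthDistribution(locus.name, {13: 1, 12: 1}), config
        ).counts == {}

    def test_normalize_forced_arithmetic(self, locus):
        norm = normalize(LengthDistribution(locus.name, {14: 20, 15: 40, 16: 10}))
        assert norm == {14: 0.5, 15: 1.0, 16: 0.25}
        assert normalize(LengthDistribution(locus.name, {15: 30})) == {15: 1.0}

    def test_normalize_empty_errors(self, locus):
        with pytest.raises(ValueError, match="nothing to normalize"):
            normalize(LengthDistribution(locus.name, {}))

    def test_vectorize_index_arithmetic(self, locus):
        cfg = PipelineConfig(window=3, min_depth=30)
        fv = vectorize({14: 0.5, 15: 1.0}, locus, cfg, depth=60)
        assert fv.evaluable
        np.testing.assert_array_equal(fv.values, [0, 0, 0.5, 1.0, 0, 0, 0])

    def test_depth_boundary(self, locus, config):
        assert not vectorize({15: 1.0}, locus, config, depth=29).evaluable
        assert vectorize({15: 1.0}, locus, config, depth=30).evaluable

    def test_out_of_window_lengths_dropped(self, locus, caplog):
        cfg = PipelineConfig(window=3)
        with caplog.at_level("WARNING"):
            fv = vectorize({15: 1.0, 40: 0.2}, locus, cfg, depth=100)
        assert fv.values.max() == 1.0
        assert fv.values.sum() == 1.0  # the outlier length contributed nothing
        assert "outside window" in caplog.text


count_maps = st.dictionaries(
    st.integers(0, 60), st.integers(1, 500), min_size=0, max_size=25
)


@settings(max_examples=300, deadline=None)
@given(count_maps)
def test_cleaning_conserves_depth_accounting(counts):
    """Kept depth + removed singleton depth == raw depth."""
    cfg = PipelineConfig()
    dist = LengthDistribution("L", counts)
    cleaned = clean_distribution(dist, cfg)
    removed = sum(c for c in counts.values() if c <= cfg.singleton_cutoff)
    assert cleaned.depth + removed == dist.depth


@settings(max_examples=300, deadline=None)
@given(count_maps.filter(lambda c: len(c) > 0))
def test_normalization_peak_is_exactly_one(counts):
    norm = normalize(LengthDistribution("L", counts))
    assert max(norm.values()) == 1.0
    assert all(0.0 < v <= 1.0 for v in norm.values())


@settings(max_examples=100, deadline=None)
@given(count_maps.filter(lambda c: len(c) > 0), st.integers(2, 20))
def test_normalization_scale_invariance(counts, factor):
    """Scaling all counts by a constant leaves the normalized profile unchanged."""
    a = normalize(LengthDistribution("L", counts))
    b = normalize(LengthDistribution("L", {k: v * factor for k, v in counts.items()}))
    assert a.keys() == b.keys()
    for k in a:
        assert a[k] == pytest.approx(b[k], abs=1e-12)


def test_features_from_distribution_depth_gate(locus, config):
    thin = LengthDistribution(locus.name, {15: 10})
    assert not features_from_distribution(thin, locus, config).evaluable
    thick = LengthDistribution(locus.name, {15: 100, 14: 20})
    fv = features_from_distribution(thick, locus, config)
    assert fv.evaluable and fv.values[config.window] == 1.0
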