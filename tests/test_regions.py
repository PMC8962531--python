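"""Reportable-range rules: padding, site addition, exclusions, coverage."""

import numpy as np
import pytest

from wgsval.intervals import Interval, IntervalSet
from wgsval.regions import (
    CoverageMatrix,
    ExclusionRuleConfig,
    TranscriptModel,
    add_sites,
    build_reportable_range,
    coverage_flag,
    pad_exons,
    scan_exclusions,
)
from wgsval.synthetic import generate_reference_fragment


# -- padding ----------------------------------------------------------------

def test_pad_exons_plus_strand():
    t = TranscriptModel("G", "chr1", "+", ((1000, 1100),))
    assert list(pad_exons(t)) == [Interval("chr1", 985, 1106)]


def test_pad_exons_minus_strand_reflects():
    t = TranscriptModel("G", "chr1", "-", ((1000, 1100),))
    assert list(pad_exons(t)) == [Interval("chr1", 994, 1115)]


def test_pad_exons_merges_overlaps_and_clamps():
    t = TranscriptModel("G", "chr1", "+", ((5, 100), (110, 200)))
    out = pad_exons(t)
    assert list(out) == [Interval("chr1", 0, 206)]


def test_strand_symmetry_of_padding():
    """Reverse-complementing the locus mirrors the padded range."""
    L = 10_000
    exons = ((1000, 1100), (2000, 2300))
    plus = pad_exons(TranscriptModel("G", "chr1", "+", exons))
    mirrored_exons = tuple(sorted((L - e, L - s) for s, e in exons))
    minus = pad_exons(TranscriptModel("G", "chr1", "-", mirrored_exons))
    assert sorted((L - iv.end, L - iv.start) for iv in minus) == [
        (iv.start, iv.end) for iv in plus
    ]


# -- site addition ----------------------------------------------------------

def test_add_sites_semantics():
    base = IntervalSet([Interval("chr1", 100, 200)])
    assert add_sites(base, plp_sites=[("chr1", 150)]) == base.merge()
    out = add_sites(base, plp_sites=[("chr1", 500)])
    assert Interval("chr1", 499, 500) in list(out)
    # 43 distinct outside sites add exactly 43 bases
    sites = [("chr1", 1000 + 10 * i) for i in range(43)]
    grown = add_sites(base, pgx_sites=sites)
    assert grown.total_bases() == base.total_bases() + 43


# -- exclusion scanning -----------------------------------------------------

def oracle_exclusions(seq, config):
    """O(n·w) per-position scan, written independently of the vectorized
    implementation."""
    n = len(seq)
    seq = seq.upper()
    mask = [False] * n
    w = config.gc_window
    for start in range(n - w + 1):
        window = seq[start : start + w]
        gc = sum(b in "GC" for b in window) / w
        if gc > config.gc_threshold:
            for p in range(start, start + w):
                mask[p] = True
    for p in range(n):
        run = 1
        while p + run < n and seq[p + run] == seq[p]:
            run += 1
        if run >= config.homopolymer_min_run:
            for q in range(p, p + run):
                mask[q] = True
    for u in config.microrepeat_units:
        for start in range(n):
            k = 0
            while start + (k + 1) * u <= n and seq[start + k * u : start + (k + 1) * u] == seq[start : start + u]:
                k += 1
            tandem = k * u
            # extend with a partial trailing unit
            extra = 0
            while (
                start + tandem + extra < n
                and seq[start + tandem + extra] == seq[start + (tandem + extra) % u]
                and tandem > 0
            ):
                extra += 1
            if tandem + extra >= u * config.microrepeat_min_units:
                for q in range(start, start + tandem + extra):
                    mask[q] = True
    return mask


def test_all_g_window_excluded():
    config = ExclusionRuleConfig(gc_window=100, gc_threshold=0.75,
                                 homopolymer_min_run=200,
                                 microrepeat_min_units=999)
    seq = "AT" * 200 + "G" * 100 + "AT" * 200
    out = scan_exclusions(seq, config)
    assert out.contains("chr1", 400) and out.contains("chr1", 499)
    assert not out.contains("chr1", 250)


def test_microrepeat_boundary():
    config = ExclusionRuleConfig(microrepeat_min_units=6, gc_window=10,
                                 gc_threshold=1.0, homopolymer_min_run=50)
    background = "GACTGCAGTC" * 20
    seq10 = background + "AT" * 10 + background
    seq5 = background + "AT" * 5 + background
    assert scan_exclusions(seq10, config).total_bases() >= 20
    assert scan_exclusions(seq5, config).total_bases() == 0


def test_homopolymer_boundary():
    config = ExclusionRuleConfig(homopolymer_min_run=10, gc_window=50,
                                 gc_threshold=1.0, microrepeat_min_units=20)
    seq = "GACTGCAGTC" * 10 + "A" * 10 + "GACTGCAGTC" * 10
    out = scan_exclusions(seq, config)
    assert out.total_bases() == 10
    seq9 = "GACTGCAGTC" * 10 + "A" * 9 + "GACTGCAGTC" * 10
    assert scan_exclusions(seq9, config).total_bases() == 0


def test_scanner_matches_brute_force_oracle():
    config = ExclusionRuleConfig(gc_window=50, gc_threshold=0.75,
                                 homopolymer_min_run=10, microrepeat_min_units=6)
    seq = generate_reference_fragment(
        5000,
        gc_target=0.55,
        homopolymer_inserts=[("T", 14, 1200), ("G", 9, 3000)],
        repeat_inserts=[("AT", 12, 2000), ("CAG", 7, 4000)],
        seed=99,
    )
    got = scan_exclusions(seq, config)
    expected = oracle_exclusions(seq, config)
    got_mask = [got.contains("chr1", p) for p in range(len(seq))]
    assert got_mask == expected


def test_named_exclusions_are_unioned():
    config = ExclusionRuleConfig(
        gc_window=10, gc_threshold=1.0, homopolymer_min_run=99,
        microrepeat_min_units=99,
        named_exclusions=IntervalSet([Interval("chr1", 5, 15, "pseudogene")]),
    )
    out = scan_exclusions("GACTGCAGTC" * 10, config)
    assert out.total_bases() == 10


# -- coverage ---------------------------------------------------------------

def _matrix(depths):
    depths = np.asarray(depths)
    return CoverageMatrix(
        chrom="chr1",
        positions=np.arange(depths.shape[0]),
        depths=depths,
        samples=[f"S{i}" for i in range(depths.shape[1])],
    )


def test_coverage_flag_constructed_pocket():
    depths = np.full((30, 10), 35)
    depths[10:20, :3] = 5  # 30% of samples low in positions 10..19
    flags = coverage_flag(_matrix(depths), depth_threshold=20, sample_fraction=0.2)
    assert list(flags) == [Interval("chr1", 10, 20)]


def test_coverage_flag_all_covered_and_boundary():
    assert len(coverage_flag(_matrix(np.full((10, 5), 30)))) == 0
    depths = np.full((5, 10), 35)
    depths[2, :2] = 5  # exactly 20% of samples low: >= rule flags it
    flags = coverage_flag(_matrix(depths), 20, 0.20)
    assert list(flags) == [Interval("chr1", 2, 3)]


def test_coverage_flag_matches_fraction_counting():
    rng = np.random.default_rng(3)
    depths = rng.poisson(25, size=(200, 20))
    flags = coverage_flag(_matrix(depths), 20, 0.25)
    for p in range(200):
        expected = (depths[p] < 20).mean() >= 0.25
        assert flags.contains("chr1", p) == expected


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        CoverageMatrix("chr1", np.arange(3), np.zeros((3, 0)), [])


# -- full builder -----------------------------------------------------------

def toy_locus():
    """Two-exon gene with one outside P/LP site and a GC exclusion overlapping
    exon 2; the expected BED is computed by hand in the assertions.  The AT
    background carries zero GC so window arithmetic is exact; repeat and
    homopolymer rules are parked out of reach to isolate the GC rule."""
    background = "AT" * 500  # 1000 bases, GC 0%
    # exon2 region [600, 700) overlaps a pure-GC block at [650, 750)
    seq = background[:650] + "GC" * 50 + background[750:]
    transcripts = [TranscriptModel("TOY", "chr1", "+", ((100, 200), (600, 700)))]
    config = ExclusionRuleConfig(gc_window=100, gc_threshold=0.75,
                                 homopolymer_min_run=200, microrepeat_min_units=400)
    return seq, transcripts, config


def test_build_toy_gene_hand_computed():
    seq, transcripts, config = toy_locus()
    rr = build_reportable_range(
        transcripts,
        plp_sites=[("chr1", 401)],  # 0-based 400, outside both exons
        reference=seq,
        exclusion_config=config,
    )
    # hand computation: exon1 [100,200) pads to [85,206); exon2 [600,700)
    # pads to [585,706).  The GC block occupies [650,750) in a GC-free
    # background, so a 100-mer window [s, s+100) holds > 75 GC bases exactly
    # when its overlap with the block exceeds 75: s in 626..674, excluding
    # positions [626, 774) and leaving [585,626) of the padded exon2.  The
    # P/LP site adds [400,401).
    assert [(iv.start, iv.end) for iv in rr.intervals] == [
        (85, 206), (400, 401), (585, 626),
    ]
    assert rr.total_bases == 121 + 1 + 41
    assert rr.conflicts == []


def test_build_site_inside_exclusion_surfaces_conflict():
    seq, transcripts, config = toy_locus()
    rr = build_reportable_range(
        transcripts,
        plp_sites=[("chr1", 700)],  # 0-based 699, inside the GC exclusion
        reference=seq,
        exclusion_config=config,
    )
    assert len(rr.conflicts) == 1
    assert not rr.intervals.contains_position("chr1", 700)


def test_build_without_rules_is_padded_exons():
    transcripts = [TranscriptModel("TOY", "chr1", "+", ((100, 200),))]
    rr = build_reportable_range(transcripts)
    assert list(rr.intervals) == [Interval("chr1", 85, 206)]


def test_build_is_a_fixpoint_with_zero_pads():
    seq, transcripts, config = toy_locus()
    rr = build_reportable_range(transcripts, reference=seq, exclusion_config=config)
    again = build_reportable_range(
        [
            TranscriptModel("RERUN", "chr1", "+",
                            tuple((iv.start, iv.end) for iv in rr.intervals))
        ],
        reference=seq,
        exclusion_config=config,
        upstream_pad=0,
        downstream_pad=0,
    )
    assert [(iv.start, iv.end) for iv in again.intervals] == [
        (iv.start, iv.end) for iv in rr.intervals
    ]
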