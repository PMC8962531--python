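"""Synthetic-cohort generation: determinism, error-rate recovery, motifs."""

import math

import numpy as np
import pytest

from wgsval.match import classify_calls
from wgsval.regions import coverage_flag
from wgsval.stats import ppa
from wgsval.synthetic import (
    SyntheticCohortConfig,
    generate_cohort,
    generate_coverage_matrix,
    generate_reference_fragment,
)


SMALL = dict(n_samples=4, region_length=20_000, n_labs=2, n_replicates_per_lab=1)


def test_config_validation():
    with pytest.raises(ValueError):
        SyntheticCohortConfig(region_length=0)
    with pytest.raises(ValueError):
        SyntheticCohortConfig(fn_rate_by_stratum={"default": 1.5})
    with pytest.raises(ValueError):
        SyntheticCohortConfig(type_mix={"snv": 0.5, "insertion": 0.2, "deletion": 0.2})


def test_same_seed_bit_identical_different_seed_differs():
    a = generate_cohort(SyntheticCohortConfig(**SMALL, seed=5))
    b = generate_cohort(SyntheticCohortConfig(**SMALL, seed=5))
    c = generate_cohort(SyntheticCohortConfig(**SMALL, seed=6))
    assert a.reference == b.reference != c.reference
    for key in a.eval_sets:
        assert a.eval_sets[key].variants == b.eval_sets[key].variants
    assert any(
        a.eval_sets[k].variants != c.eval_sets[k].variants for k in a.eval_sets
    )


def test_zero_error_rates_give_perfect_agreement():
    config = SyntheticCohortConfig(
        **SMALL,
        fn_rate_by_stratum={"default": 0.0},
        fp_rate_by_stratum={"default": 0.0},
        gt_error_rate=0.0,
        seed=3,
    )
    cohort = generate_cohort(config)
    for (lab, rep, sample), ev in cohort.eval_sets.items():
        assert ev.variants == cohort.truth[sample].variants
        c = classify_calls(cohort.truth[sample], ev, cohort.region, cohort.reference)
        assert c.counts.fp == c.counts.fn == 0
        assert ppa(c.counts) == 1.0


def test_truth_identical_across_labs_and_replicates():
    cohort = generate_cohort(SyntheticCohortConfig(**SMALL, seed=9))
    for (lab, rep, sample) in cohort.eval_sets:
        assert sample in cohort.truth


def test_eval_variants_lie_within_region():
    cohort = generate_cohort(SyntheticCohortConfig(**SMALL, seed=11))
    for ev in cohort.eval_sets.values():
        for v in ev.variants:
            assert 1 <= v.pos <= cohort.provenance.region_length
            s, e = v.footprint()
            assert e <= cohort.provenance.region_length


def test_injected_fn_rate_recovered_within_3_se():
    """Pooled PPA over >= 10k truth variants must match 1 - fn_rate within
    three binomial standard errors."""
    f = 0.05
    config = SyntheticCohortConfig(
        n_samples=100,
        region_length=120_000,
        n_labs=1,
        n_replicates_per_lab=1,
        fn_rate_by_stratum={"default": f},
        fp_rate_by_stratum={"default": 0.0},
        gt_error_rate=0.0,
        seed=17,
    )
    cohort = generate_cohort(config)
    tp = fn = 0
    for sample, truth in cohort.truth.items():
        ev = cohort.eval_sets[("lab1", "r1", sample)]
        t_keys, e_keys = truth.gt_keys(), ev.gt_keys()
        tp += len(t_keys & e_keys)
        fn += len(t_keys - e_keys)
    n = tp + fn
    assert n >= 10_000
    se = math.sqrt(f * (1 - f) / n)
    assert abs(tp / n - (1 - f)) <= 3 * se


def test_per_stratum_fn_rate_applies_to_context():
    config = SyntheticCohortConfig(
        n_samples=30,
        region_length=50_000,
        n_labs=1,
        n_replicates_per_lab=1,
        fn_rate_by_stratum={"default": 0.0, "segdup": 0.5},
        fp_rate_by_stratum={"default": 0.0},
        gt_error_rate=0.0,
        context_coverage=0.3,
        seed=23,
    )
    cohort = generate_cohort(config)
    segdup = cohort.contexts["segdup"]
    in_fn = in_total = out_fn = out_total = 0
    for sample, truth in cohort.truth.items():
        ev_keys = cohort.eval_sets[("lab1", "r1", sample)].gt_keys()
        for v in truth:
            inside = segdup.overlaps_span(v.chrom, *v.footprint())
            missing = v.gt_key not in ev_keys
            if inside:
                in_total += 1
                in_fn += missing
            else:
                out_total += 1
                out_fn += missing
    assert out_fn == 0
    assert in_total > 100
    se = math.sqrt(0.5 * 0.5 / in_total)
    assert abs(in_fn / in_total - 0.5) <= 3 * se


# -- reference fragments ----------------------------------------------------

def test_reference_fragment_motifs_and_gc():
    seq = generate_reference_fragment(
        10_000,
        gc_target=0.9,
        homopolymer_inserts=[("A", 15, 500)],
        repeat_inserts=[("AT", 10, 100)],
        seed=2,
    )
    assert seq[500:515] == "A" * 15
    assert seq[100:120] == "AT" * 10
    gc = sum(b in "GC" for b in seq) / len(seq)
    # inserts are AT-rich; exclude them from the composition check
    bg = seq[520:]
    gc_bg = sum(b in "GC" for b in bg) / len(bg)
    assert abs(gc_bg - 0.9) < 0.02


def test_reference_fragment_rejects_bad_inserts():
    with pytest.raises(ValueError, match="overlap"):
        generate_reference_fragment(
            100, homopolymer_inserts=[("A", 10, 5), ("C", 10, 10)]
        )
    with pytest.raises(ValueError):
        generate_reference_fragment(100, homopolymer_inserts=[("X", 5, 0)])
    with pytest.raises(ValueError):
        generate_reference_fragment(100, homopolymer_inserts=[("A", 50, 80)])


# -- coverage matrices ------------------------------------------------------

def test_coverage_pocket_trips_the_rule():
    m = generate_coverage_matrix(
        10, 100, mean_depth=35, low_pockets=[((10, 20), 5, 0.3)], seed=4
    )
    flags = coverage_flag(m, depth_threshold=20, sample_fraction=0.2)
    assert [(iv.start, iv.end) for iv in flags] == [(10, 20)]


def test_clean_matrix_has_no_flags():
    m = generate_coverage_matrix(20, 500, mean_depth=35, seed=6)
    assert len(coverage_flag(m, 20, 0.2)) == 0


def test_coverage_matrix_validation():
    with pytest.raises(ValueError):
        generate_coverage_matrix(0, 100)
    with pytest.raises(ValueError):
        generate_coverage_matrix(5, 100, low_pockets=[((90, 200), 5, 0.5)])
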