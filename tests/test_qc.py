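"""Degradation simulation, contamination estimation, limit of detection."""

import math

import numpy as np
import pytest
from scipy import stats as sps

from wgsval import qc
from wgsval.qc import (
    GenotypeCallerConfig,
    SiteObservation,
    call_genotype,
    contaminate,
    downsample_curve,
    duplicate_injection_curve,
    estimate_contamination,
    lod_allele_fraction,
    select_threshold,
)


def obs(depth, alt, truth="het"):
    return SiteObservation("chr1", 1, "A", "G", depth, alt, truth)


def simulate_sites(rng, n, mean_depth, truth_mix=(0.0, 0.62, 0.38), caller=None):
    caller = caller or GenotypeCallerConfig()
    af = caller.af_models
    gts = rng.choice(["hom_ref", "het", "hom_alt"], size=n, p=truth_mix)
    out = []
    for i, gt in enumerate(gts):
        depth = max(1, int(rng.poisson(mean_depth)))
        alt = int(rng.binomial(depth, af[gt]))
        out.append(SiteObservation("chr1", i + 1, "A", "G", depth, alt, gt))
    return out


# -- caller -----------------------------------------------------------------

def test_caller_examples():
    cfg = GenotypeCallerConfig(base_error=0.01)
    assert call_genotype(obs(30, 15), cfg) == "het"
    assert call_genotype(obs(30, 0), cfg) == "hom_ref"
    assert call_genotype(obs(30, 30), cfg) == "hom_alt"
    assert call_genotype(obs(0, 0), cfg) is None


@pytest.mark.parametrize("alt", range(0, 31))
def test_caller_matches_direct_pmf_argmax(alt):
    """The call must be the argmax of the three binomial likelihoods computed
    directly (hom-ref wins ties)."""
    cfg = GenotypeCallerConfig(base_error=0.01)
    pmfs = [
        sps.binom.pmf(alt, 30, p) for p in (0.01, 0.5, 0.99)
    ]
    best = max(range(3), key=lambda g: (pmfs[g], -g))
    assert call_genotype(obs(30, alt), cfg) == ["hom_ref", "het", "hom_alt"][best]


# -- downsampling -----------------------------------------------------------

def test_downsample_identity_at_full_fraction(rng):
    sites = simulate_sites(rng, 500, 35)
    curve = downsample_curve(sites, [1.0], replicates=1, seed=1)
    base = downsample_curve(sites, [1.0], replicates=1, seed=999)
    assert curve.values == base.values  # no randomness at f=1


def test_downsample_curve_monotone_and_vanishing(rng):
    sites = simulate_sites(rng, 2000, 35)
    curve = downsample_curve(
        sites, [0.02, 0.1, 0.3, 0.6, 1.0], replicates=20, seed=5
    )
    assert all(a <= b + 1e-9 for a, b in zip(curve.values, curve.values[1:]))
    assert curve.values[0] < 0.5 < curve.values[-1]


def test_downsample_validation(rng):
    with pytest.raises(ValueError):
        downsample_curve([], [0.5])
    with pytest.raises(ValueError):
        downsample_curve(simulate_sites(rng, 5, 30), [0.0])


def test_two_stage_thinning_composes(rng):
    """Thinning at f then f' must equal one thinning at f·f' in distribution
    (KS test on the resulting alt-count samples)."""
    depth, alt, n = 60, 30, 10_000
    one = rng.hypergeometric(alt, depth - alt, rng.binomial(depth, 0.32 * 0.5, n))
    stage1_d = rng.binomial(depth, 0.5, n)
    stage1_a = rng.hypergeometric(alt, depth - alt, stage1_d)
    stage2_d = rng.binomial(stage1_d, 0.32)
    two = np.array(
        [rng.hypergeometric(a, d - a, d2) for a, d, d2 in zip(stage1_a, stage1_d, stage2_d)]
    )
    assert sps.ks_2samp(one, two).pvalue > 0.01


# -- duplicates -------------------------------------------------------------

def test_duplicate_rate_zero_is_baseline(rng):
    sites = simulate_sites(rng, 500, 35)
    curve = duplicate_injection_curve(sites, [0.0], replicates=1, seed=3)
    base = downsample_curve(sites, [1.0], replicates=1, seed=3)
    assert curve.values == base.values


def test_duplicate_half_equals_downsample_half(rng):
    sites = simulate_sites(rng, 800, 35)
    dup = duplicate_injection_curve(sites, [0.5], replicates=4, seed=11)
    down = downsample_curve(sites, [0.5], replicates=4, seed=11)
    assert dup.values == down.values  # identical seed pipeline


def test_duplicate_sensitivity_non_increasing(rng):
    sites = simulate_sites(rng, 2000, 35)
    curve = duplicate_injection_curve(
        sites, [0.0, 0.3, 0.6, 0.9], replicates=10, seed=13
    )
    assert all(a >= b - 1e-9 for a, b in zip(curve.values, curve.values[1:]))


# -- contamination ----------------------------------------------------------

def hom_sites_with_het_contaminant(rng, n=5000, depth=40):
    host = simulate_sites(rng, n, depth, truth_mix=(0.5, 0.0, 0.5))
    cont = {(o.chrom, o.pos, o.ref, o.alt): "het" for o in host}
    return host, cont


def test_contaminate_alpha_zero_is_seed_stable(rng):
    host, cont = hom_sites_with_het_contaminant(rng, n=300)
    a = contaminate(host, cont, 0.0, seed=7)
    b = contaminate(host, cont, 0.0, seed=7)
    assert a == b


def test_contaminate_mixture_expectation(rng):
    """hom-ref host + hom-alt contaminant at alpha 0.5 gives mean AF near 0.5."""
    host = simulate_sites(rng, 4000, 40, truth_mix=(1.0, 0.0, 0.0))
    cont = {(o.chrom, o.pos, o.ref, o.alt): "hom_alt" for o in host}
    mixed = contaminate(host, cont, 0.5, seed=9)
    afs = [o.alt_reads / o.depth for o in mixed]
    assert np.mean(afs) == pytest.approx(0.5, abs=0.02)


def test_clean_sample_estimates_near_zero(rng):
    host, cont = hom_sites_with_het_contaminant(rng)
    est = estimate_contamination(contaminate(host, cont, 0.0, seed=2))
    assert est <= 0.01


def test_estimator_recovers_injected_alpha(rng):
    host, cont = hom_sites_with_het_contaminant(rng)
    est = estimate_contamination(contaminate(host, cont, 0.10, seed=4))
    assert est == pytest.approx(0.10, abs=0.03)


def test_estimator_requires_hom_sites(rng):
    het_only = simulate_sites(rng, 200, 40, truth_mix=(0.0, 1.0, 0.0))
    with pytest.raises(ValueError):
        estimate_contamination(het_only)


def test_genotype_error_monotone_in_alpha(rng):
    host, cont = hom_sites_with_het_contaminant(rng, n=2000)
    cfg = GenotypeCallerConfig()
    errors = []
    for alpha in (0.0, 0.05, 0.1, 0.15, 0.2, 0.3):
        mixed = contaminate(host, cont, alpha, seed=21)
        calls = [call_genotype(o, cfg) for o in mixed]
        errors.append(
            np.mean([c != o.truth_genotype for c, o in zip(calls, mixed)])
        )
    assert all(a <= b + 0.01 for a, b in zip(errors, errors[1:]))


# -- limit of detection -----------------------------------------------------

def test_lod_accuracy_at_balanced_and_low_af():
    curve = lod_allele_fraction(30, [0.05, 0.5], n_sites=4000, seed=31)
    by_level = dict(zip(curve.levels, curve.values))
    assert by_level[0.5] > 0.99
    # at AF 0.05 the het model needs >= 5 alt reads of 30; that tail is
    # P(X>=5 | Bin(30, 0.05)) ~ 0.017, so essentially all sites go hom-ref
    assert by_level[0.05] < 0.03


def test_lod_band_contains_half_at_depth_20_plus():
    for depth in (20, 30, 60):
        curve = lod_allele_fraction(
            depth, [round(x, 2) for x in np.arange(0.1, 0.91, 0.05)],
            n_sites=3000, seed=37,
        )
        assert curve.band is not None
        lo, hi = curve.band
        assert lo <= 0.5 <= hi


def test_lod_rejects_bad_grid():
    with pytest.raises(ValueError):
        lod_allele_fraction(30, [])
    with pytest.raises(ValueError):
        lod_allele_fraction(30, [0.0, 0.5])


# -- threshold selection ----------------------------------------------------

def curve_of(axis, levels, values):
    return qc.DegradationCurve(
        axis=axis, levels=levels, metric="sensitivity",
        values=values, replicates=1, seed=0,
    )


def test_select_threshold_downsample_axis():
    c = curve_of("downsample_fraction", [0.1, 0.3, 0.5, 0.8, 1.0],
                 [0.2, 0.9, 0.985, 0.995, 1.0])
    assert select_threshold(c, 0.98) == 0.5


def test_select_threshold_rate_axis():
    c = curve_of("duplicate_rate", [0.0, 0.2, 0.4, 0.6],
                 [1.0, 0.99, 0.97, 0.9])
    assert select_threshold(c, 0.98) == 0.2


def test_select_threshold_none_when_all_fail():
    c = curve_of("duplicate_rate", [0.0, 0.5], [0.5, 0.4])
    assert select_threshold(c, 0.98) is None


def test_select_threshold_stops_at_first_failure_on_non_monotone():
    # dip at 0.2 hides the later recovery: conservative prefix rule
    c = curve_of("duplicate_rate", [0.0, 0.2, 0.4], [0.99, 0.97, 0.99])
    assert select_threshold(c, 0.98) == 0.0
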