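"""QC-threshold determination by simulated degradation, plus allele-fraction
limit-of-detection analysis.

Instead of manipulating aligned reads, the module degrades site-level read
counts — the sufficient statistic a diploid genotype caller sees.  Each
:class:`SiteObservation` records total and alternate-allele read counts at one
variant site together with the truth genotype.  A minimal binomial-likelihood
caller (uniform prior over hom-ref/het/hom-alt, allele-fraction models ε, ½,
1−ε) turns counts into genotypes, and degradation curves track a metric
(sensitivity, genotype error, het-call accuracy) as coverage is thinned,
contamination mixed in, or duplicates injected.

Downsampling at fraction *f* draws a new total depth Binomial(depth, f) and
thins alternate reads hypergeometrically, which is exactly uniform removal of
reads without replacement.  Duplicate injection at rate *r* holding yield
constant leaves an effective unique depth Binomial(depth, 1 − r), so it is
the same thinning with f = 1 − r and is implemented that way.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

__all__ = [
    "GT_HOM_REF",
    "GT_HET",
    "GT_HOM_ALT",
    "SiteObservation",
    "GenotypeCallerConfig",
    "DegradationCurve",
    "call_genotype",
    "call_genotypes",
    "downsample_curve",
    "duplicate_injection_curve",
    "contaminate",
    "estimate_contamination",
    "lod_allele_fraction",
    "select_threshold",
]

GT_HOM_REF = "hom_ref"
GT_HET = "het"
GT_HOM_ALT = "hom_alt"
_GENOTYPES = (GT_HOM_REF, GT_HET, GT_HOM_ALT)


@dataclass(frozen=True)
class SiteObservation:
    chrom: str
    pos: int
    ref: str
    alt: str
    depth: int
    alt_reads: int
    truth_genotype: str

    def __post_init__(self) -> None:
        if not 0 <= self.alt_reads <= self.depth:
            raise ValueError("need 0 <= alt_reads <= depth")
        if self.truth_genotype not in _GENOTYPES:
            raise ValueError(f"unknown genotype {self.truth_genotype!r}")


@dataclass(frozen=True)
class GenotypeCallerConfig:
    """Binomial-likelihood diploid caller with uniform genotype prior."""

    base_error: float = 0.01

    def __post_init__(self) -> None:
        if not 0 < self.base_error < 0.5:
            raise ValueError("base_error must be in (0, 0.5)")

    @property
    def af_models(self) -> dict[str, float]:
        e = self.base_error
        return {GT_HOM_REF: e, GT_HET: 0.5, GT_HOM_ALT: 1.0 - e}


def call_genotype(obs: SiteObservation, config: GenotypeCallerConfig) -> str | None:
    """Argmax-likelihood genotype; ``None`` (no-call) at zero depth.

    Ties break toward hom-ref, the conservative choice that yields the fewest
    reportable calls.
    """
    if obs.depth == 0:
        return None
    return _call_counts(
        np.array([obs.alt_reads]), np.array([obs.depth]), config
    )[0]


def _call_counts(
    alt: np.ndarray, depth: np.ndarray, config: GenotypeCallerConfig
) -> list[str | None]:
    """Vectorized binomial-likelihood calls (log domain)."""
    alt = np.asarray(alt)
    depth = np.asarray(depth)
    logl = np.full((len(alt), 3), -np.inf)
    ok = depth > 0
    for g, gt in enumerate(_GENOTYPES):
        p = config.af_models[gt]
        logl[ok, g] = sps.binom.logpmf(alt[ok], depth[ok], p)
    # argmax with ties toward hom_ref: scan in genotype order, keep first max
    best = np.zeros(len(alt), dtype=int)
    best_val = logl[:, 0].copy()
    for g in (1, 2):
        better = logl[:, g] > best_val + 1e-12
        best[better] = g
        best_val[better] = logl[better, g]
    return [(_GENOTYPES[b] if o else None) for b, o in zip(best, ok)]


@dataclass
class DegradationCurve:
    axis: str  # downsample_fraction | contamination_fraction | duplicate_rate | allele_fraction
    levels: list[float]
    metric: str  # sensitivity | genotype_error_rate | het_call_accuracy
    values: list[float]
    replicates: int
    seed: int
    band: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if list(self.levels) != sorted(self.levels):
            raise ValueError("levels must be sorted ascending")


def _sensitivity(
    observations: Sequence[SiteObservation],
    alt: np.ndarray,
    depth: np.ndarray,
    config: GenotypeCallerConfig,
) -> float:
    """Fraction of non-hom-ref truth sites recalled with the exact genotype."""
    calls = _call_counts(alt, depth, config)
    num = den = 0
    for obs, call in zip(observations, calls):
        if obs.truth_genotype == GT_HOM_REF:
            continue
        den += 1
        num += call == obs.truth_genotype
    return num / den if den else math.nan


def _thinning_curve(
    observations: Sequence[SiteObservation],
    fractions: Sequence[float],
    caller: GenotypeCallerConfig,
    replicates: int,
    seed: int,
    axis: str,
    levels_out: Sequence[float],
) -> DegradationCurve:
    if not observations:
        raise ValueError("empty observation list")
    depth = np.array([o.depth for o in observations])
    alt = np.array([o.alt_reads for o in observations])
    rng = np.random.default_rng(seed)
    values = []
    for f in fractions:
        reps = []
        for _ in range(replicates):
            if f >= 1.0:
                new_depth, new_alt = depth, alt
            else:
                new_depth = rng.binomial(depth, f)
                new_alt = rng.hypergeometric(alt, depth - alt, new_depth)
            reps.append(_sensitivity(observations, new_alt, new_depth, caller))
        values.append(float(np.mean(reps)))
    order = np.argsort(levels_out)
    return DegradationCurve(
        axis=axis,
        levels=[float(levels_out[i]) for i in order],
        metric="sensitivity",
        values=[values[i] for i in order],
        replicates=replicates,
        seed=seed,
    )


def downsample_curve(
    observations: Sequence[SiteObservation],
    fractions: Sequence[float],
    caller: GenotypeCallerConfig = GenotypeCallerConfig(),
    replicates: int = 5,
    seed: int = 0,
) -> DegradationCurve:
    """Sensitivity after uniform read removal at each retained fraction."""
    if any(not 0 < f <= 1 for f in fractions):
        raise ValueError("fractions must be in (0, 1]")
    return _thinning_curve(
        observations, list(fractions), caller, replicates, seed,
        "downsample_fraction", list(fractions),
    )


def duplicate_injection_curve(
    observations: Sequence[SiteObservation],
    duplicate_rates: Sequence[float],
    caller: GenotypeCallerConfig = GenotypeCallerConfig(),
    replicates: int = 5,
    seed: int = 0,
) -> DegradationCurve:
    """Sensitivity as duplicates replace unique yield: rate r leaves unique
    depth Binomial(depth, 1 − r), identical in distribution (and, with the
    same seed, identically computed) to downsampling at f = 1 − r."""
    if any(not 0 <= r < 1 for r in duplicate_rates) :
        raise ValueError("duplicate rates must be in [0, 1)")
    fractions = [1.0 - r for r in duplicate_rates]
    return _thinning_curve(
        observations, fractions, caller, replicates, seed,
        "duplicate_rate", list(duplicate_rates),
    )


def contaminate(
    host: Sequence[SiteObservation],
    contaminant_genotypes: Mapping[tuple, str],
    alpha: float,
    seed: int = 0,
    caller: GenotypeCallerConfig = GenotypeCallerConfig(),
) -> list[SiteObservation]:
    """Mix a fraction ``alpha`` of reads from a second individual into each
    site, preserving depth.

    Each read reflects the contaminant with probability alpha, so the alt
    count is redrawn as Binomial(depth, (1−α)·AF_host + α·AF_contaminant)
    where AFs come from the caller's genotype allele-fraction models (so base
    error is included).  Site keys must match between host and contaminant.
    """
    if not 0 <= alpha < 1:
        raise ValueError("alpha must be in [0, 1)")
    missing = [
        o for o in host
        if (o.chrom, o.pos, o.ref, o.alt) not in contaminant_genotypes
    ]
    if missing:
        raise ValueError(
            f"contaminant genotypes missing for {len(missing)} sites"
        )
    rng = np.random.default_rng(seed)
    af = caller.af_models
    out = []
    for obs in host:
        cont_gt = contaminant_genotypes[(obs.chrom, obs.pos, obs.ref, obs.alt)]
        p = (1 - alpha) * af[obs.truth_genotype] + alpha * af[cont_gt]
        out.append(
            SiteObservation(
                chrom=obs.chrom,
                pos=obs.pos,
                ref=obs.ref,
                alt=obs.alt,
                depth=obs.depth,
                alt_reads=int(rng.binomial(obs.depth, p)),
                truth_genotype=obs.truth_genotype,
            )
        )
    return out


def estimate_contamination(
    observations: Sequence[SiteObservation],
    caller: GenotypeCallerConfig = GenotypeCallerConfig(),
    min_hom_sites: int = 100,
) -> float:
    """Estimate the contaminating fraction from allele balance at homozygous
    sites.

    At a homozygous site, reads disagreeing with the consensus allele come
    from sequencing error or from a contaminating individual; a contaminant
    heterozygous at the site contributes non-consensus reads at rate α/2, so
    α̂ = 2 · (median non-consensus allele fraction − base error), floored at
    zero.  Sites are selected on the truth genotype carried by the
    observations: selecting on the *called* genotype instead would truncate
    the allele-fraction distribution at the het decision boundary and bias
    the median down at higher contamination levels.
    """
    fracs = []
    for obs in observations:
        if obs.depth == 0:
            continue
        if obs.truth_genotype == GT_HOM_REF:
            fracs.append(obs.alt_reads / obs.depth)
        elif obs.truth_genotype == GT_HOM_ALT:
            fracs.append((obs.depth - obs.alt_reads) / obs.depth)
    if len(fracs) < min_hom_sites:
        raise ValueError(
            f"need >= {min_hom_sites} homozygous sites, got {len(fracs)}"
        )
    return max(0.0, 2.0 * (float(np.median(fracs)) - caller.base_error))


def lod_allele_fraction(
    depth: int,
    af_grid: Sequence[float],
    n_sites: int = 2000,
    caller: GenotypeCallerConfig = GenotypeCallerConfig(),
    seed: int = 0,
    band_threshold: float = 0.99,
) -> DegradationCurve:
    """Heterozygous-call accuracy as a function of variant allele fraction.

    Simulates ``n_sites`` het-truth sites per allele-fraction level with alt
    reads Binomial(depth, AF) and reports the fraction called het.  The
    returned curve carries a ``band``: the widest contiguous stretch of grid
    levels with accuracy ≥ ``band_threshold`` (the allele-fraction range over
    which het calls remain confident and accurate).
    """
    if not af_grid:
        raise ValueError("empty allele-fraction grid")
    if any(not 0 < a < 1 for a in af_grid):
        raise ValueError("allele fractions must be in (0, 1)")
    levels = sorted(float(a) for a in af_grid)
    rng = np.random.default_rng(seed)
    values = []
    depth_arr = np.full(n_sites, depth)
    for af in levels:
        alt = rng.binomial(depth, af, size=n_sites)
        calls = _call_counts(alt, depth_arr, caller)
        values.append(sum(c == GT_HET for c in calls) / n_sites)
    band = _widest_band(levels, values, band_threshold)
    return DegradationCurve(
        axis="allele_fraction",
        levels=levels,
        metric="het_call_accuracy",
        values=values,
        replicates=1,
        seed=seed,
        band=band,
    )


def _widest_band(
    levels: Sequence[float], values: Sequence[float], threshold: float
) -> tuple[float, float] | None:
    best: tuple[float, float] | None = None
    best_len = 0
    i = 0
    n = len(levels)
    while i < n:
        if values[i] >= threshold:
            j = i
            while j + 1 < n and values[j + 1] >= threshold:
                j += 1
            if j - i + 1 > best_len:
                best_len = j - i + 1
                best = (levels[i], levels[j])
            i = j + 1
        else:
            i += 1
    return best


def select_threshold(
    curve: DegradationCurve, min_metric: float
) -> float | None:
    """Most-degraded level still meeting ``min_metric``.

    Levels are scanned from least degraded toward most degraded (high→low for
    retained fractions, low→high for contamination/duplicate rates), stopping
    at the first failure; the level just before it is the threshold.  Returns
    ``None`` when even the least-degraded level fails.
    """
    if not curve.levels:
        raise ValueError("empty curve")
    pairs = list(zip(curve.levels, curve.values))
    if curve.axis == "downsample_fraction":
        pairs = pairs[::-1]  # highest fraction = least degraded
    selected = None
    for level, value in pairs:
        if value >= min_metric:
            selected = level
        else:
            break
    return selected
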