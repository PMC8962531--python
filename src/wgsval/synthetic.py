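"""Synthetic cohorts with controlled error structure.

The generators here stand in for the clinical and cell-line cohorts a real
validation study would sequence: truth/evaluation call-set pairs with known
per-stratum false-negative, false-positive and genotype-error rates across
multiple labs and replicates; reference fragments with engineered GC,
homopolymer and micro-repeat content; coverage matrices with planted
low-coverage pockets; and pharmacogenomic cohorts with assigned diplotypes.
Because every error is injected at a configured rate, downstream estimates
(PPA, Jaccard, contamination) can be checked against the rates that produced
them.  All randomness flows from a single integer seed through
``numpy.random.SeedSequence`` spawning, so identical configs give
bit-identical cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np

from .intervals import Interval, IntervalSet
from .pgx import StarAlleleDefinitionTable
from .regions import CoverageMatrix
from .variants import CallSet, GT_HET, GT_HOM_ALT, Variant

__all__ = [
    "SyntheticCohortConfig",
    "SyntheticCohort",
    "generate_cohort",
    "generate_reference_fragment",
    "generate_coverage_matrix",
    "generate_pgx_cohort",
]

_BASES = np.array(list("ACGT"))


@dataclass(frozen=True)
class SyntheticCohortConfig:
    """Study conditions for one synthetic validation cohort.

    Defaults describe a desk-scale analogue of a multi-center clinical
    validation: three labs running duplicate replicates over a ~200 kb
    reportable-range-sized region, a human-typical small-variant density of
    about one call per kilobase with an SNV-dominated type mix, roughly
    two-thirds heterozygous calls, and small baseline error rates.
    ``fn_rate_by_stratum`` / ``fp_rate_by_stratum`` keys may be ``default``,
    a variant type (``snv``/``insertion``/``deletion``) or a context label;
    the largest applicable rate wins for FN, and FP rates are false calls per
    base of the region.
    """

    n_samples: int = 12
    region_length: int = 200_000
    variant_rate: float = 1e-3
    type_mix: Mapping[str, float] = field(
        default_factory=lambda: {"snv": 0.85, "insertion": 0.07, "deletion": 0.08}
    )
    indel_geom_p: float = 0.35  # truncated geometric on 1..50
    max_indel_length: int = 50
    het_fraction: float = 0.62
    fn_rate_by_stratum: Mapping[str, float] = field(
        default_factory=lambda: {"default": 0.002}
    )
    fp_rate_by_stratum: Mapping[str, float] = field(
        default_factory=lambda: {"default": 2e-6}
    )
    gt_error_rate: float = 0.001
    n_labs: int = 3
    n_replicates_per_lab: int = 2
    gc_content: float = 0.41
    context_labels: tuple[str, ...] = ("segdup", "low_complexity")
    context_coverage: float = 0.10  # fraction of region per context track
    seed: int = 0

    def __post_init__(self) -> None:
        if self.region_length <= 0:
            raise ValueError("region_length must be positive")
        if self.n_samples <= 0 or self.n_labs <= 0 or self.n_replicates_per_lab <= 0:
            raise ValueError("counts must be positive")
        if abs(sum(self.type_mix.values()) - 1.0) > 1e-9:
            raise ValueError("type_mix must sum to 1")
        for name, rate in [
            ("variant_rate", self.variant_rate),
            ("het_fraction", self.het_fraction),
            ("gt_error_rate", self.gt_error_rate),
            *[(f"fn[{k}]", v) for k, v in self.fn_rate_by_stratum.items()],
            *[(f"fp[{k}]", v) for k, v in self.fp_rate_by_stratum.items()],
        ]:
            if not 0 <= rate <= 1:
                raise ValueError(f"{name} must be in [0, 1], got {rate}")


@dataclass
class SyntheticCohort:
    truth: dict[str, CallSet]
    eval_sets: dict[tuple[str, str, str], CallSet]  # (lab, replicate, sample)
    contexts: dict[str, IntervalSet]
    reference: str
    region: IntervalSet
    coverage: CoverageMatrix
    provenance: SyntheticCohortConfig

    @property
    def chrom(self) -> str:
        return "chr1"


def generate_reference_fragment(
    length: int,
    gc_target: float = 0.41,
    homopolymer_inserts: Sequence[tuple[str, int, int]] = (),
    repeat_inserts: Sequence[tuple[str, int, int]] = (),
    seed: int = 0,
) -> str:
    """Random sequence at a target GC fraction with motifs planted at fixed
    positions.

    ``homopolymer_inserts`` are (base, run_length, position); ``repeat_inserts``
    are (unit, n_units, position).  Inserts must fit inside the fragment and
    must not overlap one another.
    """
    if length <= 0:
        raise ValueError("length must be positive")
    spans = []
    for base, run, pos in homopolymer_inserts:
        if base not in "ACGT":
            raise ValueError(f"invalid base {base!r}")
        spans.append((pos, pos + run, base * run))
    for unit, n_units, pos in repeat_inserts:
        if not unit or any(b not in "ACGT" for b in unit):
            raise ValueError(f"invalid repeat unit {unit!r}")
        spans.append((pos, pos + len(unit) * n_units, unit * n_units))
    spans.sort()
    prev_end = 0
    for start, end, _ in spans:
        if start < prev_end:
            raise ValueError("overlapping inserts")
        if end > length:
            raise ValueError("insert extends past fragment end")
        prev_end = end

    rng = np.random.default_rng(seed)
    p = np.array(
        [(1 - gc_target) / 2, gc_target / 2, gc_target / 2, (1 - gc_target) / 2]
    )
    seq = rng.choice(_BASES, size=length, p=p)
    for start, end, motif in spans:
        seq[start:end] = list(motif)
    return "".join(seq)


def generate_coverage_matrix(
    n_samples: int,
    positions: int,
    mean_depth: float = 35.0,
    low_pockets: Sequence[tuple[tuple[int, int], int, float]] = (),
    seed: int = 0,
    chrom: str = "chr1",
) -> CoverageMatrix:
    """Per-site depths Poisson(mean_depth), with pockets ((start, end), depth,
    affected_sample_fraction) forced to the stated depth in the first
    ``fraction`` of samples (rounded up)."""
    if n_samples <= 0:
        raise ValueError("need at least one sample")
    if positions <= 0:
        raise ValueError("need at least one position")
    if mean_depth < 0:
        raise ValueError("negative depths are meaningless")
    rng = np.random.default_rng(seed)
    depths = rng.poisson(mean_depth, size=(positions, n_samples))
    for (start, end), depth, frac in low_pockets:
        if depth < 0:
            raise ValueError("negative pocket depth")
        if not (0 <= start < end <= positions):
            raise ValueError(f"pocket [{start}, {end}) outside position range")
        k = int(np.ceil(frac * n_samples))
        affected = rng.choice(n_samples, size=k, replace=False)
        depths[start:end, affected] = depth
    return CoverageMatrix(
        chrom=chrom,
        positions=np.arange(positions),
        depths=depths,
        samples=[f"S{i:03d}" for i in range(n_samples)],
    )


# ---------------------------------------------------------------------------
# cohort generation


def _truncated_geometric(rng: np.random.Generator, p: float, high: int, size: int) -> np.ndarray:
    """Geometric on 1..high by rejection-free inverse transform."""
    u = rng.random(size)
    # CDF of geometric truncated at high
    cmax = 1 - (1 - p) ** high
    lengths = np.ceil(np.log1p(-u * cmax) / np.log1p(-p)).astype(int)
    return np.clip(lengths, 1, high)


def _pos_high(config: SyntheticCohortConfig) -> int:
    """Highest admissible 1-based variant position (exclusive): keeps indel
    footprints inside the fragment.  Small regions fall back to leaving a
    single-base tail."""
    return max(3, config.region_length - config.max_indel_length - 1)


def _draw_truth(
    rng: np.random.Generator,
    config: SyntheticCohortConfig,
    reference: str,
    sample: str,
) -> list[Variant]:
    """Place truth variants uniformly at random with non-overlapping
    footprints, leaving one base of slack so indels remain left-alignable."""
    n_target = rng.binomial(config.region_length, config.variant_rate)
    types = list(config.type_mix)
    probs = np.array([config.type_mix[t] for t in types])
    chosen = rng.choice(len(types), size=n_target, p=probs)
    lengths = _truncated_geometric(
        rng, config.indel_geom_p, config.max_indel_length, n_target
    )
    variants: list[Variant] = []
    occupied: set[int] = set()
    for t_idx, L in zip(chosen, lengths):
        vtype = types[t_idx]
        for _ in range(30):  # rejection sampling for a free footprint
            # avoid pos 1 (no left-extension room) and the fragment tail
            pos = int(rng.integers(2, _pos_high(config)))
            span = range(pos - 1, pos + (L if vtype == "deletion" else 1) + 1)
            if occupied.isdisjoint(span):
                break
        else:
            continue
        occupied.update(span)
        anchor = reference[pos - 1]
        gt = GT_HET if rng.random() < config.het_fraction else GT_HOM_ALT
        if vtype == "snv":
            alt = str(rng.choice([b for b in "ACGT" if b != anchor]))
            v = Variant("chr1", pos, anchor, alt, gt, sample)
        elif vtype == "insertion":
            ins = "".join(rng.choice(_BASES, size=int(L)))
            v = Variant("chr1", pos, anchor, anchor + ins, gt, sample)
        else:
            L = min(int(L), len(reference) - pos)
            if L < 1:
                continue
            ref = reference[pos - 1 : pos + L]
            v = Variant("chr1", pos, ref, anchor, gt, sample)
        variants.append(v)
    return sorted(variants)


def _variant_type(v: Variant) -> str:
    if v.is_snv:
        return "snv"
    return "insertion" if v.is_insertion else "deletion"


def _stratum_rate(
    v: Variant, rates: Mapping[str, float], contexts: Mapping[str, IntervalSet]
) -> float:
    applicable = [rates.get("default", 0.0), rates.get(_variant_type(v), 0.0)]
    for label, ivs in contexts.items():
        if label in rates and ivs.overlaps_span(v.chrom, *v.footprint()):
            applicable.append(rates[label])
    return max(applicable)


def _make_contexts(
    rng: np.random.Generator, config: SyntheticCohortConfig
) -> dict[str, IntervalSet]:
    contexts: dict[str, IntervalSet] = {}
    n_blocks = 10
    block = max(1, int(config.region_length * config.context_coverage / n_blocks))
    for label in config.context_labels:
        starts = rng.integers(0, config.region_length - block, size=n_blocks)
        contexts[label] = IntervalSet(
            [Interval("chr1", int(s), int(s) + block, label) for s in starts]
        ).merge()
    return contexts


def _derive_eval(
    rng: np.random.Generator,
    truth: list[Variant],
    config: SyntheticCohortConfig,
    contexts: Mapping[str, IntervalSet],
    reference: str,
    occupied_sites: set[int],
    sample: str,
) -> list[Variant]:
    out: list[Variant] = []
    for v in truth:
        if rng.random() < _stratum_rate(v, config.fn_rate_by_stratum, contexts):
            continue  # dropped: false negative
        if rng.random() < config.gt_error_rate:
            flipped = GT_HOM_ALT if v.genotype == GT_HET else GT_HET
            v = Variant(v.chrom, v.pos, v.ref, v.alt, flipped, sample)
        out.append(v)
    # false calls at reference positions not in truth, same type mix;
    # 'default' and type-keyed rates apply across the region, context-keyed
    # rates to the bases of that context
    types = list(config.type_mix)
    probs = np.array([config.type_mix[t] for t in types])
    taken = set(occupied_sites) | {v.pos for v in out}
    pos_hi = _pos_high(config)
    for key, rate in sorted(config.fp_rate_by_stratum.items()):
        if rate <= 0:
            continue
        context = contexts.get(key) if key in contexts else None
        n_bases = context.total_bases() if context is not None else config.region_length
        n_fp = rng.binomial(n_bases, rate)
        for _ in range(n_fp):
            if key in config.type_mix:
                vtype = key
            else:
                vtype = types[int(rng.choice(len(types), p=probs))]
            for _ in range(30):
                if context is not None:
                    covered = context.covered_positions("chr1")
                    pos = int(covered[rng.integers(len(covered))]) + 1
                    if not 2 <= pos < pos_hi:
                        continue
                else:
                    pos = int(rng.integers(2, pos_hi))
                if pos not in taken:
                    break
            else:
                continue
            taken.add(pos)
            anchor = reference[pos - 1]
            gt = GT_HET if rng.random() < config.het_fraction else GT_HOM_ALT
            if vtype == "snv":
                alt = str(rng.choice([b for b in "ACGT" if b != anchor]))
                out.append(Variant("chr1", pos, anchor, alt, gt, sample))
            elif vtype == "insertion":
                L = int(_truncated_geometric(rng, config.indel_geom_p, config.max_indel_length, 1)[0])
                ins = "".join(rng.choice(_BASES, size=L))
                out.append(Variant("chr1", pos, anchor, anchor + ins, gt, sample))
            else:
                L = int(_truncated_geometric(rng, config.indel_geom_p, config.max_indel_length, 1)[0])
                L = min(L, len(reference) - pos)
                out.append(Variant("chr1", pos, reference[pos - 1 : pos + L], anchor, gt, sample))
    return sorted(out)


def generate_cohort(config: SyntheticCohortConfig) -> SyntheticCohort:
    """Generate truth and per-(lab, replicate) evaluation call sets plus the
    supporting reference, contexts and coverage matrix.

    Truth is identical across labs and replicates for a sample; each
    evaluation set independently drops truth variants (per-stratum FN rate),
    flips zygosity at the truth site (genotype error), and adds false calls
    (FP rate per base).
    """
    root = np.random.SeedSequence(config.seed)
    ss_ref, ss_ctx, ss_truth, ss_eval, ss_cov = root.spawn(5)
    reference = generate_reference_fragment(
        config.region_length,
        gc_target=config.gc_content,
        seed=int(ss_ref.generate_state(1)[0] % (2**31)),
    )
    rng_ctx = np.random.default_rng(ss_ctx)
    contexts = _make_contexts(rng_ctx, config)
    region = IntervalSet([Interval("chr1", 0, config.region_length)])

    samples = [f"S{i:03d}" for i in range(config.n_samples)]
    truth: dict[str, CallSet] = {}
    truth_rngs = ss_truth.spawn(config.n_samples)
    for sample, ss in zip(samples, truth_rngs):
        variants = _draw_truth(np.random.default_rng(ss), config, reference, sample)
        truth[sample] = CallSet(sample=sample, variants=variants)

    eval_sets: dict[tuple[str, str, str], CallSet] = {}
    labs = [f"lab{i + 1}" for i in range(config.n_labs)]
    reps = [f"r{i + 1}" for i in range(config.n_replicates_per_lab)]
    eval_seeds = ss_eval.spawn(config.n_labs * config.n_replicates_per_lab * config.n_samples)
    idx = 0
    for lab in labs:
        for rep in reps:
            for sample in samples:
                rng = np.random.default_rng(eval_seeds[idx])
                idx += 1
                occupied = {v.pos for v in truth[sample]}
                variants = _derive_eval(
                    rng, truth[sample].variants, config, contexts,
                    reference, occupied, sample,
                )
                eval_sets[(lab, rep, sample)] = CallSet(
                    sample=sample, variants=variants, lab=lab, replicate=rep
                )

    coverage = generate_coverage_matrix(
        n_samples=config.n_samples,
        positions=min(config.region_length, 5000),
        seed=int(ss_cov.generate_state(1)[0] % (2**31)),
    )
    return SyntheticCohort(
        truth=truth,
        eval_sets=eval_sets,
        contexts=contexts,
        reference=reference,
        region=region,
        coverage=coverage,
        provenance=config,
    )


def generate_pgx_cohort(
    definitions: StarAlleleDefinitionTable,
    diplotype_assignments: Mapping[str, tuple[str, str]],
    seed: int = 0,
) -> dict[str, CallSet]:
    """Call sets carrying exactly the defining variants of each sample's two
    assigned star alleles: a variant shared by both haplotypes is homozygous,
    one carried by a single haplotype heterozygous."""
    out: dict[str, CallSet] = {}
    for sample, (a, b) in sorted(diplotype_assignments.items()):
        for name in (a, b):
            if name not in definitions.alleles:
                raise KeyError(f"unknown allele {name!r} for sample {sample!r}")
        ka, kb = definitions.alleles[a], definitions.alleles[b]
        variants = []
        for key in sorted(ka | kb):
            gt = GT_HOM_ALT if key in ka and key in kb else GT_HET
            chrom, pos, ref, alt = key
            variants.append(Variant(chrom, pos, ref, alt, gt, sample))
        out[sample] = CallSet(sample=sample, variants=variants)
    return out
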