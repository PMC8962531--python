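"""Genotype-aware comparison of an evaluation call set against a truth set.

This is the package's replacement for a vcfeval-style comparison engine,
restricted to normalized small variants.  A true positive requires an exact
match on (chrom, pos, ref, alt, genotype); a call with the right alternate
allele but the wrong zygosity is, by default, counted once as a false positive
and once as a false negative (the truth genotype was missed and a different
genotype was asserted).  True negatives are positional: every base of the
comparison region not touched by any truth or evaluation call footprint is a
concordantly negative position.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Iterable, Mapping, Sequence

from .intervals import IntervalSet
from .variants import CallSet, Variant, normalize_callset

__all__ = [
    "ContingencyCounts",
    "ClassifiedCalls",
    "classify_calls",
    "stratify",
    "detect_recurrent_artifacts",
    "VARIANT_PREDICATES",
]


@dataclass
class ContingencyCounts:
    """TP/FP/FN/TN counts for one stratum of one comparison."""

    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0
    stratum: str = "all"

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be non-negative")

    def __add__(self, other: "ContingencyCounts") -> "ContingencyCounts":
        return ContingencyCounts(
            tp=self.tp + other.tp,
            fp=self.fp + other.fp,
            fn=self.fn + other.fn,
            tn=self.tn + other.tn,
            stratum=self.stratum if self.stratum == other.stratum else "pooled",
        )


@dataclass
class ClassifiedCalls:
    sample: str
    tp: list[Variant]
    fp: list[Variant]
    fn: list[Variant]
    counts: ContingencyCounts
    region: IntervalSet

    def discordant_site_keys(self) -> frozenset[tuple]:
        return frozenset(v.site_key for v in self.fp) | frozenset(
            v.site_key for v in self.fn
        )


def _in_region(v: Variant, region: IntervalSet) -> bool:
    return region.contains_position(v.chrom, v.pos)


def _touched_positions(variants: Iterable[Variant], region: IntervalSet) -> set:
    """Distinct 0-based (chrom, pos) covered by variant footprints ∩ region."""
    touched = set()
    for v in variants:
        start, end = v.footprint()
        for p in range(start, end):
            if region.contains(v.chrom, p):
                touched.add((v.chrom, p))
    return touched


def classify_calls(
    truth: CallSet,
    eval_calls: CallSet,
    region: IntervalSet,
    reference: str | None = None,
    gt_mismatch: str = "fp_and_fn",
) -> ClassifiedCalls:
    """Classify evaluation calls against truth within a comparison region.

    Parameters
    ----------
    truth, eval_calls
        Call sets for the same sample.  If ``reference`` is given both are
        normalized first; otherwise they are assumed already normalized.
    region
        Comparison region (0-based half-open intervals).  Calls whose
        normalized position falls outside are ignored entirely.
    gt_mismatch
        ``"fp_and_fn"`` (default) counts a genotype mismatch at a shared site
        as one FP plus one FN; ``"fp_only"`` counts only the FP, reproducing
        the stricter reading in which the truth entry is considered found.
    """
    if truth.sample != eval_calls.sample:
        raise ValueError(
            f"mixed-sample comparison: {truth.sample!r} vs {eval_calls.sample!r}"
        )
    if not region:
        raise ValueError("comparison region is empty")
    if gt_mismatch not in ("fp_and_fn", "fp_only"):
        raise ValueError(f"unknown gt_mismatch mode {gt_mismatch!r}")
    if reference is not None:
        truth = normalize_callset(truth, reference)
        eval_calls = normalize_callset(eval_calls, reference)

    t_in = [v for v in truth if _in_region(v, region)]
    e_in = [v for v in eval_calls if _in_region(v, region)]
    t_keys = {v.gt_key: v for v in t_in}
    e_keys = {v.gt_key: v for v in e_in}
    e_sites = {v.site_key for v in e_in}

    tp = sorted(v for k, v in t_keys.items() if k in e_keys)
    fp = sorted(v for k, v in e_keys.items() if k not in t_keys)
    fn = sorted(v for k, v in t_keys.items() if k not in e_keys)
    if gt_mismatch == "fp_only":
        # a truth entry whose site is called with a different genotype is
        # dropped from FN; the wrong-genotype call stays FP
        fn = [v for v in fn if v.site_key not in e_sites]

    touched = _touched_positions([*t_in, *e_in], region)
    tn = region.total_bases() - len(touched)
    counts = ContingencyCounts(tp=len(tp), fp=len(fp), fn=len(fn), tn=tn)
    return ClassifiedCalls(
        sample=truth.sample, tp=tp, fp=fp, fn=fn, counts=counts, region=region
    )


# ---------------------------------------------------------------------------
# stratification

VARIANT_PREDICATES: dict[str, Callable[[Variant], bool]] = {
    "snv": lambda v: v.is_snv,
    "insertion": lambda v: v.is_insertion,
    "deletion": lambda v: v.is_deletion,
    "indel": lambda v: not v.is_snv,
    "het": lambda v: v.genotype == "het",
    "hom_alt": lambda v: v.genotype == "hom_alt",
}


def _overlaps_context(v: Variant, context: IntervalSet) -> bool:
    start, end = v.footprint()
    return context.overlaps_span(v.chrom, start, end)


def stratify(
    classified: ClassifiedCalls,
    contexts: Mapping[str, IntervalSet] | None = None,
    variant_predicates: Sequence[str] = (),
) -> dict[str, ContingencyCounts]:
    """Partition classified calls into (overlapping) genomic-context and
    variant-type strata, in the style of a stratified accuracy table.

    Strata are not mutually exclusive: each TP/FP/FN is counted in every
    context whose intervals its footprint overlaps and under every satisfied
    predicate.  Per-context TN is recomputed over context ∩ region.
    """
    contexts = dict(contexts or {})
    out: dict[str, ContingencyCounts] = {"all": classified.counts}
    for name, context in contexts.items():
        sub_region = classified.region.intersect(context)
        tp = [v for v in classified.tp if _overlaps_context(v, context)]
        fp = [v for v in classified.fp if _overlaps_context(v, context)]
        fn = [v for v in classified.fn if _overlaps_context(v, context)]
        touched = _touched_positions(
            [*tp, *fp, *fn], sub_region
        )
        out[name] = ContingencyCounts(
            tp=len(tp),
            fp=len(fp),
            fn=len(fn),
            tn=sub_region.total_bases() - len(touched),
            stratum=name,
        )
    for name in variant_predicates:
        try:
            pred = VARIANT_PREDICATES[name]
        except KeyError:
            raise KeyError(f"unknown variant predicate {name!r}") from None
        tp = [v for v in classified.tp if pred(v)]
        fp = [v for v in classified.fp if pred(v)]
        fn = [v for v in classified.fn if pred(v)]
        touched = _touched_positions([*tp, *fp, *fn], classified.region)
        out[name] = ContingencyCounts(
            tp=len(tp),
            fp=len(fp),
            fn=len(fn),
            tn=classified.region.total_bases() - len(touched),
            stratum=name,
        )
    return out


def detect_recurrent_artifacts(
    classified_per_sample: Sequence[ClassifiedCalls],
    min_fraction: float = 0.20,
) -> set[tuple]:
    """Site keys discordant (FP or FN) in at least ``min_fraction`` of samples.

    Recurrent discordances across many samples point at systematic artifacts
    (mapping or homology issues) rather than per-sample errors; callers may
    exclude the returned keys and re-classify.  The threshold is inclusive
    (exactly the fraction counts).
    """
    if not 0 < min_fraction <= 1:
        raise ValueError("min_fraction must be in (0, 1]")
    if len(classified_per_sample) < 2:
        raise ValueError("need at least 2 samples to detect recurrence")
    n = len(classified_per_sample)
    counts: dict[tuple, int] = {}
    for c in classified_per_sample:
        for key in c.discordant_site_keys():
            counts[key] = counts.get(key, 0) + 1
    return {key for key, k in counts.items() if k / n >= min_fraction}
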