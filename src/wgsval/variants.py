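"""Variant and call-set containers plus representation normalization.

A :class:`Variant` is one diploid small-variant call: chromosome, 1-based
position, reference and alternate allele strings, and an unphased zygosity
(``het`` or ``hom_alt``).  Homozygous-reference is implicit — the absence of a
call.  Normalization brings equivalent representations to a canonical form so
that set comparisons between call sets are meaningful: indels are left-aligned
against the reference and trimmed to a single anchor base, and multi-base
substitutions are decomposed into per-base SNVs.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Iterable, Iterator

__all__ = [
    "GT_HET",
    "GT_HOM_ALT",
    "Variant",
    "CallSet",
    "ReferenceMismatchError",
    "normalize",
    "normalize_callset",
]

GT_HET = "het"
GT_HOM_ALT = "hom_alt"
_VALID_GT = frozenset({GT_HET, GT_HOM_ALT})


class ReferenceMismatchError(ValueError):
    """The variant's REF allele disagrees with the reference sequence."""


@dataclass(frozen=True, order=True)
class Variant:
    chrom: str
    pos: int  # 1-based, VCF convention
    ref: str
    alt: str
    genotype: str = GT_HET
    sample: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"pos must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        if self.ref == self.alt:
            raise ValueError("ref and alt must differ")
        if self.genotype not in _VALID_GT:
            raise ValueError(f"genotype must be one of {sorted(_VALID_GT)}")

    # -- keys --------------------------------------------------------------
    @property
    def site_key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    @property
    def gt_key(self) -> tuple[str, int, str, str, str]:
        """Exact-match key: site plus genotype."""
        return (self.chrom, self.pos, self.ref, self.alt, self.genotype)

    # -- classification ----------------------------------------------------
    @property
    def is_snv(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1

    @property
    def is_insertion(self) -> bool:
        return len(self.alt) > len(self.ref)

    @property
    def is_deletion(self) -> bool:
        return len(self.ref) > len(self.alt)

    @property
    def event_length(self) -> int:
        """SNVs have length 1; indels the number of inserted/deleted bases."""
        return max(abs(len(self.ref) - len(self.alt)), 1)

    def footprint(self) -> tuple[int, int]:
        """0-based half-open reference span touched by this call."""
        return (self.pos - 1, self.pos - 1 + len(self.ref))


@dataclass
class CallSet:
    """All calls for one sample, with lab/replicate provenance."""

    sample: str
    variants: list[Variant] = field(default_factory=list)
    lab: str | None = None
    replicate: str | None = None

    def __post_init__(self) -> None:
        seen: set[tuple] = set()
        for v in self.variants:
            if v.site_key in seen:
                raise ValueError(f"duplicate site {v.site_key} in call set")
            seen.add(v.site_key)

    def __len__(self) -> int:
        return len(self.variants)

    def __iter__(self) -> Iterator[Variant]:
        return iter(self.variants)

    def gt_keys(self) -> frozenset[tuple]:
        return frozenset(v.gt_key for v in self.variants)

    def site_keys(self) -> frozenset[tuple]:
        return frozenset(v.site_key for v in self.variants)


# ---------------------------------------------------------------------------
# normalization


def _trim_and_left_align(
    pos: int, ref: str, alt: str, reference: str
) -> tuple[int, str, str]:
    """Left-align an indel against ``reference`` (0-based string for pos 1..n).

    Classic parsimony algorithm: repeatedly strip a shared trailing base,
    extending to the left with reference sequence when an allele empties, then
    strip shared leading bases keeping one anchor.
    """
    while True:
        if ref and alt and ref[-1] == alt[-1] and (len(ref) > 1 or len(alt) > 1):
            ref, alt = ref[:-1], alt[:-1]
            if not ref or not alt:
                if pos == 1:
                    raise ValueError("cannot left-extend past the start of the reference")
                pos -= 1
                base = reference[pos - 1]
                ref, alt = base + ref, base + alt
            continue
        break
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return pos, ref, alt


def normalize(variant: Variant, reference: str) -> list[Variant]:
    """Canonicalize one variant against a reference sequence.

    Returns a list because multi-base substitutions decompose into one SNV per
    mismatching base (each inheriting the original genotype).  SNVs pass
    through unchanged; indels come back left-aligned with a single anchor
    base.  ``reference`` is the full sequence of ``variant.chrom`` (so 1-based
    position ``p`` reads ``reference[p - 1]``).

    Raises :class:`ReferenceMismatchError` when the REF allele does not match
    the reference sequence — the signal for corrupt input.
    """
    expected = reference[variant.pos - 1 : variant.pos - 1 + len(variant.ref)]
    if expected.upper() != variant.ref.upper():
        raise ReferenceMismatchError(
            f"{variant.chrom}:{variant.pos} REF {variant.ref!r} != reference {expected!r}"
        )
    pos, ref, alt = _trim_and_left_align(
        variant.pos, variant.ref.upper(), variant.alt.upper(), reference.upper()
    )
    if len(ref) == len(alt):
        out = []
        for i, (r, a) in enumerate(zip(ref, alt)):
            if r != a:
                out.append(replace(variant, pos=pos + i, ref=r, alt=a))
        return out
    return [replace(variant, pos=pos, ref=ref, alt=alt)]


def normalize_callset(callset: CallSet, reference: str) -> CallSet:
    """Normalize every variant; decomposed SNVs that collide on a site are
    deduplicated (identical representations of the same event)."""
    seen: dict[tuple, Variant] = {}
    for v in callset.variants:
        for n in normalize(v, reference):
            seen.setdefault(n.site_key, n)
    return CallSet(
        sample=callset.sample,
        variants=sorted(seen.values()),
        lab=callset.lab,
        replicate=callset.replicate,
    )
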