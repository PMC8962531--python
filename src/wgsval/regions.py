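"""Reportable-range construction for a clinical sequencing assay.

The reportable range is the interval set within which the assay commits to
returning results.  It is assembled rule by rule:

1. exons of the selected transcript for each gene, padded into the introns
   (−15 bases transcription-upstream, +6 downstream by default, strand-aware);
2. single-base additions for known pathogenic/likely-pathogenic (P/LP)
   variants and pharmacogenomic star-allele sites falling outside the padded
   exons;
3. subtraction of technically challenging sequence: named exclusions (e.g.
   pseudogene-homology regions), high-GC windows, long homopolymers, and
   di-/tri-nucleotide micro-repeats;
4. annotation (not subtraction) of regions that fail a cohort-level coverage
   rule — positions lacking the depth threshold in too large a fraction of
   samples.

Sites removed by an exclusion are surfaced in a conflict report rather than
silently decided either way.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .intervals import Interval, IntervalSet

__all__ = [
    "TranscriptModel",
    "ExclusionRuleConfig",
    "ReportableRange",
    "CoverageMatrix",
    "pad_exons",
    "add_sites",
    "scan_exclusions",
    "coverage_flag",
    "build_reportable_range",
]


@dataclass(frozen=True)
class TranscriptModel:
    """Exon structure of one gene's selected transcript."""

    gene: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # 0-based half-open, sorted

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError("strand must be '+' or '-'")
        prev_end = -1
        for start, end in self.exons:
            if start < 0 or end <= start:
                raise ValueError(f"invalid exon [{start}, {end})")
            if start < prev_end:
                raise ValueError("exons must be sorted and non-overlapping")
            prev_end = end


@dataclass(frozen=True)
class ExclusionRuleConfig:
    gc_threshold: float = 0.75
    gc_window: int = 100
    homopolymer_min_run: int = 10
    microrepeat_units: tuple[int, ...] = (2, 3)
    microrepeat_min_units: int = 6
    named_exclusions: IntervalSet = field(default_factory=IntervalSet)

    def __post_init__(self) -> None:
        if self.gc_window <= 0:
            raise ValueError("gc_window must be positive")
        if not 0 < self.gc_threshold <= 1:
            raise ValueError("gc_threshold must be in (0, 1]")


@dataclass
class CoverageMatrix:
    """Per-site sequencing depth across samples (positions × samples)."""

    chrom: str
    positions: np.ndarray  # 0-based, sorted
    depths: np.ndarray  # shape (n_positions, n_samples)
    samples: list[str]

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=int)
        self.depths = np.asarray(self.depths)
        if self.depths.ndim != 2 or self.depths.shape != (
            len(self.positions),
            len(self.samples),
        ):
            raise ValueError("depth matrix shape must be (positions, samples)")
        if len(self.samples) < 1 or len(self.positions) < 1:
            raise ValueError("coverage matrix needs at least one sample and position")
        if (self.depths < 0).any():
            raise ValueError("negative depths")

    @property
    def n_samples(self) -> int:
        return len(self.samples)


@dataclass
class ReportableRange:
    intervals: IntervalSet
    annotations: dict[str, IntervalSet]
    exclusions_applied: list[tuple[str, Interval]]
    coverage_flags: IntervalSet
    conflicts: list[str]
    total_bases: int


def pad_exons(
    transcript: TranscriptModel, upstream_pad: int = 15, downstream_pad: int = 6
) -> IntervalSet:
    """Pad each exon into the flanking introns, strand-aware.

    "Upstream" is in transcription direction: for a plus-strand gene the
    upstream pad extends to lower genomic coordinates; for a minus-strand gene
    it extends to higher ones.  Overlapping padded exons merge; pads are
    clamped at coordinate 0.
    """
    if transcript.strand == "+":
        left, right = upstream_pad, downstream_pad
    else:
        left, right = downstream_pad, upstream_pad
    out = [
        Interval(transcript.chrom, max(0, start - left), end + right)
        for start, end in transcript.exons
    ]
    return IntervalSet(out).merge()


def add_sites(
    base: IntervalSet,
    plp_sites: Sequence[tuple[str, int]] = (),
    pgx_sites: Sequence[tuple[str, int]] = (),
) -> IntervalSet:
    """Add single-base intervals for (chrom, 1-based position) sites not
    already covered; covered sites are no-ops."""
    extra = []
    for chrom, pos1 in [*plp_sites, *pgx_sites]:
        if not base.contains_position(chrom, pos1):
            extra.append(Interval(chrom, pos1 - 1, pos1))
    if not extra:
        return base.merge()
    return base.union(IntervalSet(extra))


def _runs_to_intervals(chrom: str, mask: np.ndarray) -> IntervalSet:
    """Convert a boolean per-position mask into merged intervals."""
    if not mask.any():
        return IntervalSet()
    padded = np.concatenate(([False], mask, [False]))
    edges = np.flatnonzero(np.diff(padded.astype(np.int8)))
    starts, ends = edges[::2], edges[1::2]
    return IntervalSet(
        [Interval(chrom, int(s), int(e)) for s, e in zip(starts, ends)]
    )


def scan_exclusions(
    reference: str,
    config: ExclusionRuleConfig = ExclusionRuleConfig(),
    chrom: str = "chr1",
) -> IntervalSet:
    """Union of the technically challenging regions in a reference fragment.

    Excluded are: named exclusions from the config; every position covered by
    a sliding window (step 1) whose GC fraction strictly exceeds the
    threshold; homopolymer runs at least ``homopolymer_min_run`` long; and
    tandem repeats of a 2- or 3-base unit with at least
    ``microrepeat_min_units`` complete units.
    """
    n = len(reference)
    w = config.gc_window
    if w > n:
        raise ValueError("gc_window longer than reference fragment")
    seq = reference.upper()
    mask = np.zeros(n, dtype=bool)

    # (b) high-GC sliding windows
    gc = np.frombuffer(seq.encode(), dtype=np.uint8)
    is_gc = (gc == ord("G")) | (gc == ord("C"))
    window_gc = np.convolve(is_gc.astype(float), np.ones(w), mode="valid") / w
    hot = window_gc > config.gc_threshold
    for start in np.flatnonzero(hot):
        mask[start : start + w] = True

    # (c) homopolymer runs
    run_start = 0
    for i in range(1, n + 1):
        if i == n or seq[i] != seq[run_start]:
            if i - run_start >= config.homopolymer_min_run:
                mask[run_start:i] = True
            run_start = i

    # (d) micro-repeats: maximal tandem stretches of a u-mer
    for u in config.microrepeat_units:
        min_len = u * config.microrepeat_min_units
        i = 0
        while i + u <= n:
            j = i
            while j + u < n and seq[j + u] == seq[j]:
                j += 1
            stretch = j - i + u  # total repeated-region length
            if stretch >= min_len:
                mask[i : i + stretch] = True
                i = i + stretch - u + 1
            else:
                i += 1

    out = _runs_to_intervals(chrom, mask)
    named = IntervalSet(
        [iv for iv in config.named_exclusions if iv.chrom == chrom]
    )
    return out.union(named)


def coverage_flag(
    matrix: CoverageMatrix,
    depth_threshold: int = 20,
    sample_fraction: float = 0.20,
) -> IntervalSet:
    """Positions where at least ``sample_fraction`` of samples fall below
    ``depth_threshold`` depth, as merged intervals (boundary inclusive)."""
    if matrix.n_samples < 1:
        raise ValueError("coverage matrix has no samples")
    frac_low = (matrix.depths < depth_threshold).mean(axis=1)
    low = frac_low >= sample_fraction - 1e-12
    # positions may be non-contiguous; flag per position then merge adjacency
    flagged = matrix.positions[low]
    if flagged.size == 0:
        return IntervalSet()
    mask = np.zeros(int(matrix.positions.max()) + 2, dtype=bool)
    mask[flagged] = True
    return _runs_to_intervals(matrix.chrom, mask)


def build_reportable_range(
    transcripts: Sequence[TranscriptModel],
    plp_sites: Sequence[tuple[str, int]] = (),
    pgx_sites: Sequence[tuple[str, int]] = (),
    reference: str | None = None,
    exclusion_config: ExclusionRuleConfig | None = None,
    coverage_matrix: CoverageMatrix | None = None,
    upstream_pad: int = 15,
    downstream_pad: int = 6,
    reference_chrom: str = "chr1",
) -> ReportableRange:
    """Run the full rule pipeline: pad → add sites → subtract exclusions →
    annotate coverage flags.  Deterministic given its inputs."""
    padded = IntervalSet()
    for t in transcripts:
        padded = padded.union(pad_exons(t, upstream_pad, downstream_pad))
    with_sites = add_sites(padded, plp_sites, pgx_sites)

    exclusions = IntervalSet()
    if exclusion_config is not None and reference is not None:
        exclusions = scan_exclusions(reference, exclusion_config, reference_chrom)
    elif exclusion_config is not None:
        exclusions = exclusion_config.named_exclusions.merge()

    final = with_sites.subtract(exclusions)

    conflicts = []
    for kind, sites in (("plp", plp_sites), ("pgx", pgx_sites)):
        for chrom, pos1 in sites:
            if exclusions.contains_position(chrom, pos1):
                conflicts.append(
                    f"{kind} site {chrom}:{pos1} falls inside an exclusion "
                    "and is absent from the final range"
                )

    applied = [
        ("exclusion", iv)
        for iv in exclusions.intersect(with_sites)
    ]
    flags = (
        coverage_flag(coverage_matrix)
        if coverage_matrix is not None
        else IntervalSet()
    )
    annotations = {
        "exon_padded": padded,
        "plp_site": IntervalSet(
            [Interval(c, p - 1, p, "plp_site") for c, p in plp_sites]
        ),
        "pgx_site": IntervalSet(
            [Interval(c, p - 1, p, "pgx_site") for c, p in pgx_sites]
        ),
    }
    return ReportableRange(
        intervals=final,
        annotations=annotations,
        exclusions_applied=applied,
        coverage_flags=flags.intersect(final),
        conflicts=conflicts,
        total_bases=final.total_bases(),
    )
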