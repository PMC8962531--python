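"""Readers and writers for the plain-text formats the pipeline exchanges.

Supported formats: a minimal single-sample VCF 4.2 subset (GT-only FORMAT, no
phasing, no symbolic alleles; multi-allelic records are split on read), BED
(0-based half-open, optional label in column 4), FASTA, per-site coverage TSV
(rows = positions, columns = samples) and YAML cohort configs.  Coordinate
conversion between VCF's 1-based positions and the 0-based half-open
convention used internally happens here and nowhere else.  Writers accept a
``seed`` recorded as a header comment so every emitted file carries its
provenance.
"""

from __future__ import annotations

import logging
import warnings
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .intervals import Interval, IntervalSet
from .regions import CoverageMatrix
from .synthetic import SyntheticCohortConfig
from .variants import CallSet, GT_HET, GT_HOM_ALT, Variant

__all__ = [
    "read_vcf",
    "write_vcf",
    "read_bed",
    "write_bed",
    "read_fasta",
    "write_fasta",
    "read_coverage_tsv",
    "write_coverage_tsv",
    "read_cohort_config",
    "write_cohort_config",
]

logger = logging.getLogger("wgsval")


# ---------------------------------------------------------------------------
# VCF


def write_vcf(callset: CallSet, path: str | Path, seed: int | None = None) -> None:
    """Write one sample's calls as minimal VCF 4.2 (CHROM POS ID REF ALT QUAL
    FILTER INFO FORMAT GT), sorted by (chrom, pos)."""
    lines = ["##fileformat=VCFv4.2", "##source=wgsval"]
    if seed is not None:
        lines.append(f"##wgsval_seed={seed}")
    for chrom in dict.fromkeys(v.chrom for v in sorted(callset.variants)):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">')
    sample = callset.sample or "SAMPLE"
    lines.append(
        "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + sample
    )
    for v in sorted(callset.variants):
        gt = "0/1" if v.genotype == GT_HET else "1/1"
        lines.append(
            f"{v.chrom}\t{v.pos}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t.\tGT\t{gt}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_vcf(path: str | Path) -> CallSet:
    """Read a single-sample VCF into a CallSet.

    Multi-allelic records split into one variant per alternate allele, with
    zygosity taken from the allele's dose in GT (1/2 → two heterozygous
    variants).  Records with fully missing GT are skipped with a warning;
    half-calls (one missing allele) are rejected.
    """
    path = Path(path)
    with pysam.VariantFile(str(path)) as vf:
        samples = list(vf.header.samples)
        if len(samples) != 1:
            raise ValueError(
                f"{path.name}: expected exactly one sample column, found {samples}"
            )
        sample = samples[0]
        variants: list[Variant] = []
        for rec in vf:
            call = rec.samples[sample]
            alleles = call.allele_indices
            if alleles is None or all(a is None for a in alleles):
                logger.warning("%s:%s missing GT, record skipped", rec.chrom, rec.pos)
                continue
            if any(a is None for a in alleles):
                raise ValueError(
                    f"{path.name} {rec.chrom}:{rec.pos}: half-call GT is not supported"
                )
            for alt_idx, alt in enumerate(rec.alts or (), start=1):
                dose = sum(a == alt_idx for a in alleles)
                if dose == 0:
                    continue
                gt = GT_HOM_ALT if dose == 2 else GT_HET
                variants.append(
                    Variant(rec.chrom, rec.pos, rec.ref, alt, gt, sample)
                )
    order = [(v.chrom, v.pos) for v in variants]
    if order != sorted(order):
        logger.warning("%s: records were unsorted; sorted on read", path.name)
    variants.sort()
    return CallSet(sample=sample, variants=variants)


# ---------------------------------------------------------------------------
# BED


def write_bed(intervals: IntervalSet, path: str | Path, seed: int | None = None) -> None:
    lines = []
    if seed is not None:
        lines.append(f"# wgsval_seed={seed}")
    for iv in intervals:
        cols = [iv.chrom, str(iv.start), str(iv.end)]
        if iv.label:
            cols.append(iv.label)
        lines.append("\t".join(cols))
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))


def read_bed(path: str | Path, merge: bool = False) -> IntervalSet:
    out = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith(("#", "track", "browser")):
            continue
        fields = line.split("\t")
        if len(fields) < 3:
            raise ValueError(f"{path}:{lineno}: BED needs at least 3 columns")
        try:
            start, end = int(fields[1]), int(fields[2])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: non-numeric coordinates") from exc
        if start >= end:
            raise ValueError(f"{path}:{lineno}: start >= end")
        label = fields[3] if len(fields) > 3 else ""
        out.append(Interval(fields[0], start, end, label))
    ivs = IntervalSet(out)
    return ivs.merge() if merge else ivs


# ---------------------------------------------------------------------------
# FASTA


def write_fasta(sequences: Mapping[str, str], path: str | Path, seed: int | None = None) -> None:
    records = [
        SeqRecord(
            Seq(seq),
            id=name,
            description=f"wgsval_seed={seed}" if seed is not None else "",
        )
        for name, seq in sequences.items()
    ]
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path: str | Path) -> dict[str, str]:
    return {rec.id: str(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}


# ---------------------------------------------------------------------------
# coverage TSV


def write_coverage_tsv(matrix: CoverageMatrix, path: str | Path, seed: int | None = None) -> None:
    frame = pd.DataFrame(matrix.depths, columns=matrix.samples)
    frame.insert(0, "position", matrix.positions)
    frame.insert(0, "chrom", matrix.chrom)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# wgsval_seed={seed}\n")
        frame.to_csv(fh, sep="\t", index=False)


def read_coverage_tsv(path: str | Path) -> CoverageMatrix:
    frame = pd.read_csv(path, sep="\t", comment="#")
    chroms = frame["chrom"].unique()
    if len(chroms) != 1:
        raise ValueError("coverage TSV must cover a single chromosome")
    samples = [c for c in frame.columns if c not in ("chrom", "position")]
    return CoverageMatrix(
        chrom=str(chroms[0]),
        positions=frame["position"].to_numpy(),
        depths=frame[samples].to_numpy(),
        samples=samples,
    )


# ---------------------------------------------------------------------------
# YAML config


def write_cohort_config(config: SyntheticCohortConfig, path: str | Path) -> None:
    from dataclasses import asdict

    data = asdict(config)
    data["type_mix"] = dict(data["type_mix"])
    data["context_labels"] = list(data["context_labels"])
    Path(path).write_text(yaml.safe_dump(data, sort_keys=True))


def read_cohort_config(path: str | Path) -> SyntheticCohortConfig:
    data = yaml.safe_load(Path(path).read_text())
    data["context_labels"] = tuple(data.get("context_labels", ()))
    return SyntheticCohortConfig(**data)
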