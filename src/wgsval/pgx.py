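"""Rule-based pharmacogenomic star-allele diplotype calling and concordance.

Star alleles are named haplotypes (*2, *17, ...) defined by a set of core
variants; the reference allele (*1 by convention) is the empty set.  This is
a transparent rule-based caller over unphased genotype calls: it finds
alleles whose entire defining set is present, resolves zygosity into a
diplotype, and flags any configuration it cannot resolve as ambiguous rather
than guessing.  Structural-variant alleles and read-backed phasing are out of
scope; genes on a haploid chromosome (e.g. G6PD in males) are handled by an
explicit ploidy argument, never by sex inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .variants import CallSet, GT_HET, GT_HOM_ALT, Variant

__all__ = [
    "StarAlleleDefinitionTable",
    "DiplotypeCall",
    "call_star_alleles",
    "tabulate_concordance",
    "definitions_from_frame",
]

SiteKey = tuple[str, int, str, str]


@dataclass(frozen=True)
class StarAlleleDefinitionTable:
    gene: str
    alleles: Mapping[str, frozenset[SiteKey]]
    reference_allele: str = "*1"

    def __post_init__(self) -> None:
        alleles = dict(self.alleles)
        if self.reference_allele not in alleles:
            alleles[self.reference_allele] = frozenset()
            object.__setattr__(self, "alleles", alleles)
        if alleles[self.reference_allele]:
            raise ValueError("reference allele must have an empty defining set")
        for name, keys in alleles.items():
            if name != self.reference_allele and not keys:
                raise ValueError(f"allele {name} has an empty defining set")

    @property
    def non_reference(self) -> list[str]:
        return sorted(a for a in self.alleles if a != self.reference_allele)

    def defined_sites(self) -> frozenset[SiteKey]:
        out: set[SiteKey] = set()
        for keys in self.alleles.values():
            out |= keys
        return frozenset(out)


@dataclass
class DiplotypeCall:
    gene: str
    alleles: tuple[str, ...]  # unordered; length == ploidy
    ambiguous: bool = False
    conflicts: list[str] = field(default_factory=list)

    @property
    def name(self) -> str:
        return "/".join(sorted(self.alleles))


def call_star_alleles(
    calls: CallSet,
    table: StarAlleleDefinitionTable,
    ploidy: int = 2,
) -> DiplotypeCall:
    """Assign a star-allele diplotype from normalized variant calls.

    Resolution rules, applied over alleles whose defining variants are all
    present:

    * all defining variants homozygous → the allele sits on both haplotypes;
    * all defining variants heterozygous and exactly one allele matched →
      allele / reference;
    * two distinct alleles fully matched heterozygous → allele / allele,
      flagged ambiguous because an unphased genotype cannot rule out both
      variants sharing one haplotype (the trans interpretation is preferred);
    * nested definitions: the largest fully matched set wins, ties ambiguous;
    * partial matches or leftover variants at defined sites → ambiguous with
      conflicts listed.
    """
    if ploidy not in (1, 2):
        raise ValueError("ploidy must be 1 or 2")
    gt_by_site = {v.site_key: v.genotype for v in calls}
    unknown = [
        k for k in gt_by_site if k not in table.defined_sites()
    ]
    conflicts = [f"call at undefined site {k}" for k in sorted(unknown)]

    full_hom: list[str] = []
    full_het: list[str] = []
    full_mixed: list[str] = []
    partial: list[str] = []
    for name in table.non_reference:
        keys = table.alleles[name]
        present = [k for k in keys if k in gt_by_site]
        if not present:
            continue
        if len(present) < len(keys):
            partial.append(name)
            continue
        gts = {gt_by_site[k] for k in keys}
        if gts == {GT_HOM_ALT}:
            full_hom.append(name)
        elif gts == {GT_HET}:
            full_het.append(name)
        else:
            full_mixed.append(name)

    ref = table.reference_allele
    explained: set[SiteKey] = set()

    def keep_largest(names: list[str]) -> tuple[list[str], bool]:
        """Drop alleles nested inside a larger fully-matched allele; report
        whether a size tie between non-identical sets forced ambiguity."""
        kept, tie = [], False
        for n in names:
            sup = [
                m for m in names
                if m != n and table.alleles[n] < table.alleles[m]
            ]
            if not sup:
                kept.append(n)
        sizes = [len(table.alleles[n]) for n in kept]
        if len(kept) > 1 and len(set(sizes)) < len(sizes):
            tie = True
        return kept, tie

    ambiguous = bool(partial or unknown)
    for name in partial:
        keys = table.alleles[name]
        missing = [k for k in keys if k not in gt_by_site]
        conflicts.append(
            f"allele {name} partially matched ({len(keys) - len(missing)}/"
            f"{len(keys)} defining variants present)"
        )

    if ploidy == 1:
        candidates = full_hom + full_mixed + full_het
        candidates, tie = keep_largest(candidates)
        if tie:
            ambiguous = True
        allele = candidates[0] if candidates else ref
        if len(candidates) > 1:
            ambiguous = True
            conflicts.append(f"multiple alleles matched on haploid gene: {candidates}")
        return DiplotypeCall(table.gene, (allele,), ambiguous, conflicts)

    if full_hom:
        homs, tie = keep_largest(full_hom)
        ambiguous |= tie
        a = max(homs, key=lambda n: len(table.alleles[n]))
        explained |= table.alleles[a]
        hets, tie2 = keep_largest(full_het)
        ambiguous |= tie2
        hets = [h for h in hets if not (table.alleles[h] & explained)]
        if not hets and not (set(gt_by_site) - explained - set(unknown)):
            return DiplotypeCall(table.gene, (a, a), ambiguous, conflicts)
        # hom core plus extra het variants: a/b if exactly one het allele
        # explains the remainder
        if len(hets) == 1:
            b = hets[0]
            if not (set(gt_by_site) - explained - table.alleles[b] - set(unknown)):
                conflicts.append(
                    f"hom {a} with het {b}: cis configuration cannot be excluded"
                )
                return DiplotypeCall(table.gene, (a, b), True, conflicts)
        conflicts.append(f"unexplained variants beyond homozygous allele {a}")
        return DiplotypeCall(table.gene, (a, a), True, conflicts)

    cands, tie = keep_largest(full_het + full_mixed)
    ambiguous |= tie
    cands = sorted(cands, key=lambda n: (-len(table.alleles[n]), n))
    defined_calls = set(gt_by_site) - set(unknown)
    if not cands:
        return DiplotypeCall(
            table.gene, (ref, ref), ambiguous or bool(gt_by_site), conflicts
        )
    if len(cands) == 1 and cands[0] in full_het:
        a = cands[0]
        leftover = defined_calls - table.alleles[a]
        if leftover:
            ambiguous = True
            conflicts.append(f"variants unexplained by {a}: {sorted(leftover)}")
        return DiplotypeCall(table.gene, (a, ref), ambiguous, conflicts)

    # pair scan: an unordered allele pair (a, b) explains the calls when
    # sites in both defining sets are hom, sites in exactly one are het,
    # and nothing else is called at defined sites
    consistent: list[tuple[str, str]] = []
    for i, a in enumerate(cands):
        for b in cands[i + 1 :]:
            ka, kb = table.alleles[a], table.alleles[b]
            expected = {k: GT_HOM_ALT for k in ka & kb}
            expected.update({k: GT_HET for k in ka ^ kb})
            if {k: gt_by_site[k] for k in defined_calls} == expected:
                consistent.append((a, b))
    if len(consistent) == 1:
        a, b = consistent[0]
        conflicts.append(
            f"het {a} + het {b}: cis configuration cannot be excluded"
        )
        return DiplotypeCall(table.gene, (a, b), True, conflicts)
    if consistent:
        a, b = consistent[0]
        conflicts.append(
            f"multiple consistent allele pairs: {consistent}"
        )
        return DiplotypeCall(table.gene, (a, b), True, conflicts)
    conflicts.append(f"unresolved heterozygous allele combination: {cands}")
    if cands[0] in full_mixed:
        conflicts.append(f"allele {cands[0]} matched with mixed zygosity")
    pair = (cands[0], cands[1]) if len(cands) > 1 else (cands[0], ref)
    return DiplotypeCall(table.gene, pair, True, conflicts)


def tabulate_concordance(
    truth_diplotypes: Mapping[str, DiplotypeCall],
    method_calls: Mapping[tuple[str, str], DiplotypeCall],
) -> pd.DataFrame:
    """Concordance of diplotype calls against truth, per truth diplotype row
    and per method, with a pooled overall fraction.

    ``method_calls`` maps (method, sample) → call.  Correctness is exact
    unordered diplotype equality.  Output has one row per (gene, diplotype)
    plus per-method correct/incorrect columns, and ``overall_num`` /
    ``overall_den`` whose column sums give the pooled concordance.
    """
    methods = sorted({m for m, _ in method_calls})
    if not methods:
        raise ValueError("no method calls supplied")
    rows: dict[tuple[str, str], dict] = {}
    for (method, sample), call in sorted(method_calls.items()):
        truth = truth_diplotypes.get(sample)
        if truth is None:
            raise KeyError(f"sample {sample!r} missing from truth diplotypes")
        key = (truth.gene, truth.name)
        row = rows.setdefault(
            key,
            {
                "gene": truth.gene,
                "diplotype": truth.name,
                "n_samples": set(),
                **{f"{m}_correct": 0 for m in methods},
                **{f"{m}_incorrect": 0 for m in methods},
            },
        )
        row["n_samples"].add(sample)
        correct = sorted(call.alleles) == sorted(truth.alleles)
        row[f"{method}_correct" if correct else f"{method}_incorrect"] += 1
    out = []
    for (_, _), row in sorted(rows.items()):
        row["n_samples"] = len(row["n_samples"])
        row["overall_num"] = sum(row[f"{m}_correct"] for m in methods)
        row["overall_den"] = row["overall_num"] + sum(
            row[f"{m}_incorrect"] for m in methods
        )
        out.append(row)
    return pd.DataFrame(out)


def definitions_from_frame(frame: pd.DataFrame) -> dict[str, StarAlleleDefinitionTable]:
    """Build per-gene definition tables from a tidy frame with columns
    gene, allele, chrom, pos, ref, alt (one defining variant per row)."""
    tables = {}
    for gene, sub in frame.groupby("gene"):
        alleles: dict[str, set] = {}
        for _, r in sub.iterrows():
            alleles.setdefault(str(r["allele"]), set()).add(
                (str(r["chrom"]), int(r["pos"]), str(r["ref"]), str(r["alt"]))
            )
        tables[str(gene)] = StarAlleleDefinitionTable(
            gene=str(gene),
            alleles={k: frozenset(v) for k, v in alleles.items()},
        )
    return tables
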