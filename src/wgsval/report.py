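"""End-to-end demo pipeline: one seeded synthetic cohort through every stage.

``run_validation`` ties the stages together the way a validation report is
organised — accuracy (stratified PPA/NPA), precision (pairwise Jaccard and
the interlab equivalence test), reportable range, QC simulation with a
selected threshold, limit of detection, and PGx concordance — and returns a
nested dict in which every number is the output of a stage computation on the
generated cohort.  Intended for examples, smoke tests and reproduction runs;
real analyses call the stage functions directly.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict
from typing import Any

import numpy as np

from . import qc
from .intervals import Interval, IntervalSet
from .match import classify_calls, stratify
from .pgx import StarAlleleDefinitionTable, call_star_alleles, tabulate_concordance
from .precision import pairwise_jaccard, test_interlab_equivalence
from .regions import ExclusionRuleConfig, TranscriptModel, build_reportable_range
from .stats import agreement_table
from .synthetic import (
    SyntheticCohortConfig,
    generate_cohort,
    generate_coverage_matrix,
    generate_pgx_cohort,
    generate_reference_fragment,
)

__all__ = ["run_validation", "demo_pgx_table"]


def demo_pgx_table() -> StarAlleleDefinitionTable:
    """A five-allele toy definition table with pairwise disjoint defining
    sets (synthetic stand-in for a curated star-allele catalogue)."""
    mk = lambda pos, ref, alt: ("chr10", pos, ref, alt)
    return StarAlleleDefinitionTable(
        gene="CYP2C19",
        alleles={
            "*1": frozenset(),
            "*2": frozenset({mk(1000, "G", "A")}),
            "*3": frozenset({mk(2000, "G", "A"), mk(2100, "C", "T")}),
            "*9": frozenset({mk(3000, "G", "A")}),
            "*17": frozenset({mk(4000, "C", "T")}),
        },
    )


def _accuracy_section(cohort, seed: int) -> dict[str, Any]:
    per_stratum: dict[str, Any] = {}
    classified = []
    lab, rep = "lab1", "r1"
    for sample, truth in cohort.truth.items():
        ev = cohort.eval_sets[(lab, rep, sample)]
        classified.append(
            classify_calls(truth, ev, cohort.region, cohort.reference)
        )
    pooled: dict[str, Any] = {}
    for c in classified:
        strata = stratify(
            c, cohort.contexts, variant_predicates=("snv", "insertion", "deletion", "het", "hom_alt")
        )
        for name, counts in strata.items():
            pooled[name] = pooled.get(name, counts.__class__(stratum=name)) + counts
    table = agreement_table(pooled)
    return {"table": table, "classified": classified}


def run_validation(
    config: SyntheticCohortConfig | None = None, seed: int = 0
) -> dict[str, Any]:
    """Run the full pipeline on a synthetic cohort; all randomness derives
    from ``seed``."""
    if config is None:
        config = SyntheticCohortConfig(
            n_samples=5,
            region_length=100_000,
            fn_rate_by_stratum={"default": 0.01},
            fp_rate_by_stratum={"default": 5e-6},
            gt_error_rate=0.002,
            seed=seed,
        )
    cohort = generate_cohort(config)
    report: dict[str, Any] = {
        "provenance": {
            "seed": seed,
            "config": asdict(config),
            "config_sha256": hashlib.sha256(
                repr(sorted(asdict(config).items())).encode()
            ).hexdigest(),
        }
    }

    # accuracy
    acc = _accuracy_section(cohort, seed)
    report["accuracy"] = {"agreement_table": acc["table"]}

    # precision
    matrix = pairwise_jaccard(cohort.eval_sets, cohort.region)
    equiv = test_interlab_equivalence(matrix, n_permutations=2000, seed=seed + 1)
    report["precision"] = {
        "jaccard_matrix": matrix.to_frame(),
        "mean_within": equiv.mean_within,
        "mean_between": equiv.mean_between,
        "p_value": equiv.p_value,
    }

    # reportable range on a toy two-gene locus over a dedicated fragment
    rr_ref = generate_reference_fragment(
        6000,
        gc_target=0.40,
        homopolymer_inserts=[("A", 14, 2500)],
        repeat_inserts=[("AT", 10, 4200)],
        seed=seed + 2,
    )
    transcripts = [
        TranscriptModel("GENE1", "chr1", "+", ((500, 700), (1200, 1500))),
        TranscriptModel("GENE2", "chr1", "-", ((3000, 3300), (4100, 4400))),
    ]
    coverage = generate_coverage_matrix(
        10, 6000, mean_depth=35,
        low_pockets=[((600, 640), 5, 0.3)],
        seed=seed + 3,
    )
    rr = build_reportable_range(
        transcripts,
        plp_sites=[("chr1", 2001)],
        pgx_sites=[("chr1", 5001)],
        reference=rr_ref,
        exclusion_config=ExclusionRuleConfig(),
        coverage_matrix=coverage,
    )
    report["reportable_range"] = {
        "total_bases": rr.total_bases,
        "n_intervals": len(rr.intervals),
        "n_exclusions_applied": len(rr.exclusions_applied),
        "n_coverage_flags": len(rr.coverage_flags),
        "conflicts": rr.conflicts,
    }

    # QC simulation + limit of detection
    rng = np.random.default_rng(seed + 4)
    caller = qc.GenotypeCallerConfig()
    obs = _simulate_observations(rng, n_sites=1500, mean_depth=35, caller=caller)
    curve = qc.downsample_curve(
        obs, fractions=[0.1, 0.2, 0.4, 0.6, 0.8, 1.0],
        caller=caller, replicates=3, seed=seed + 5,
    )
    threshold = qc.select_threshold(curve, min_metric=0.98)
    lod = qc.lod_allele_fraction(
        depth=35, af_grid=[round(x, 2) for x in np.arange(0.05, 0.96, 0.05)],
        n_sites=2000, caller=caller, seed=seed + 6,
    )
    report["qc"] = {
        "downsample_curve": list(zip(curve.levels, curve.values)),
        "selected_downsample_threshold": threshold,
        "lod_band": lod.band,
    }

    # PGx concordance: three methods re-calling generated cohorts
    table = demo_pgx_table()
    alleles = sorted(table.alleles)
    sample_names = [f"P{i:02d}" for i in range(20)]
    rng_pgx = np.random.default_rng(seed + 7)
    assignments = {
        s: tuple(sorted(rng_pgx.choice(alleles, size=2, replace=True)))
        for s in sample_names
    }
    callsets = generate_pgx_cohort(table, assignments, seed=seed + 8)
    truth_calls = {
        s: call_star_alleles(cs, table) for s, cs in callsets.items()
    }
    method_calls = {
        (method, s): call_star_alleles(cs, table)
        for method in ("centerA", "centerB", "centerC")
        for s, cs in callsets.items()
    }
    conc = tabulate_concordance(truth_calls, method_calls)
    report["pgx"] = {
        "concordance_table": conc,
        "overall": (int(conc["overall_num"].sum()), int(conc["overall_den"].sum())),
    }
    return report


def _simulate_observations(rng, n_sites: int, mean_depth: float, caller) -> list:
    """Het/hom-alt truth sites with Poisson depths and binomial alt counts."""
    af = caller.af_models
    out = []
    for i in range(n_sites):
        gt = qc.GT_HET if rng.random() < 0.62 else qc.GT_HOM_ALT
        depth = max(1, int(rng.poisson(mean_depth)))
        alt = int(rng.binomial(depth, af[gt]))
        out.append(
            qc.SiteObservation("chr1", i + 1, "A", "G", depth, alt, gt)
        )
    return out
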