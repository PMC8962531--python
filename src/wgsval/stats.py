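"""Positive/negative percent agreement with confidence intervals.

PPA = TP / (TP + FN) and NPA = TN / (TN + FP) are the sensitivity and
specificity analogues used when the comparator assay is itself imperfect
rather than a gold standard.  Point estimates may be pooled across samples
(micro-average of the counts) or averaged per sample (macro); intervals come
either from the normal approximation on per-sample values (mean ± z·SD/√n) or
from a binomial Wald/Wilson interval on the pooled proportion.

Undefined proportions (zero denominator) are returned as ``nan`` rather than
raised, so stratified tables with empty strata stay rectangular.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.proportion import proportion_confint

from .match import ClassifiedCalls, ContingencyCounts

__all__ = [
    "CIConfig",
    "AgreementResult",
    "ppa",
    "npa",
    "ci_normal_per_sample",
    "ci_pooled",
    "accuracy_by_event_length",
    "agreement_table",
    "round_half_up",
]


@dataclass(frozen=True)
class CIConfig:
    z: float = 1.96
    clamp: bool = True

    def __post_init__(self) -> None:
        if self.z <= 0:
            raise ValueError("z must be positive")


@dataclass
class AgreementResult:
    stratum: str
    ppa: float
    npa: float
    ppa_ci: tuple[float, float]
    npa_ci: tuple[float, float]
    method: str = "pooled"
    ci_method: str = "wilson_pooled"
    n_samples: int = 1


def ppa(counts: ContingencyCounts) -> float:
    """TP / (TP + FN); ``nan`` when no truth positives exist."""
    denom = counts.tp + counts.fn
    return counts.tp / denom if denom else math.nan


def npa(counts: ContingencyCounts) -> float:
    """TN / (TN + FP); ``nan`` when no negative positions exist."""
    denom = counts.tn + counts.fp
    return counts.tn / denom if denom else math.nan


def _clamp(lo: float, hi: float, config: CIConfig) -> tuple[float, float]:
    if config.clamp:
        return (max(lo, 0.0), min(hi, 1.0))
    return (lo, hi)


def ci_normal_per_sample(
    per_sample_values: Sequence[float], config: CIConfig = CIConfig()
) -> tuple[float, float]:
    """Normal-approximation interval on per-sample proportions:
    mean ± z · (sample SD / √n).  Requires n ≥ 2."""
    values = [v for v in per_sample_values if not math.isnan(v)]
    n = len(values)
    if n < 2:
        raise ValueError("per-sample CI needs at least 2 samples")
    mean = float(np.mean(values))
    half = config.z * float(np.std(values, ddof=1)) / math.sqrt(n)
    return _clamp(mean - half, mean + half, config)


def ci_pooled(
    counts: ContingencyCounts,
    which: str = "ppa",
    method: str = "wilson",
    config: CIConfig = CIConfig(),
) -> tuple[float, float]:
    """Binomial interval (Wald via ``normal``, or Wilson) on the pooled
    proportion."""
    if which == "ppa":
        k, n = counts.tp, counts.tp + counts.fn
    elif which == "npa":
        k, n = counts.tn, counts.tn + counts.fp
    else:
        raise ValueError("which must be 'ppa' or 'npa'")
    if n == 0:
        raise ValueError(f"{which} denominator is zero")
    alpha = 2.0 * (1.0 - 0.5 * (1.0 + math.erf(config.z / math.sqrt(2.0))))
    sm_method = {"wald": "normal", "wilson": "wilson"}.get(method)
    if sm_method is None:
        raise ValueError("method must be 'wald' or 'wilson'")
    lo, hi = proportion_confint(k, n, alpha=alpha, method=sm_method)
    return _clamp(float(lo), float(hi), config)


def accuracy_by_event_length(
    classified: ClassifiedCalls, max_length: int = 50
) -> pd.DataFrame:
    """PPA per event length; SNVs occupy their own 'snv' category and indels
    bin by inserted/deleted bases 1..max_length.  Empty bins report ``nan``."""
    rows = []
    bins: list[object] = ["snv", *range(1, max_length + 1)]
    tally = {b: [0, 0] for b in bins}  # bin -> [tp, fn]
    for v in classified.tp:
        b = "snv" if v.is_snv else min(v.event_length, max_length)
        tally[b][0] += 1
    for v in classified.fn:
        b = "snv" if v.is_snv else min(v.event_length, max_length)
        tally[b][1] += 1
    for b in bins:
        tp, fn = tally[b]
        rows.append(
            {
                "length": b,
                "tp": tp,
                "fn": fn,
                "ppa": tp / (tp + fn) if tp + fn else math.nan,
            }
        )
    return pd.DataFrame(rows)


def round_half_up(x: float, digits: int = 2) -> float:
    """Round with ties away from zero, matching printed-table conventions
    (Python's bankers' rounding would turn 0.125 into 0.12)."""
    factor = 10.0 ** digits
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


def agreement_table(
    strata_counts: Mapping[str, ContingencyCounts],
    per_sample: Mapping[str, Sequence[ContingencyCounts]] | None = None,
    config: CIConfig = CIConfig(),
    ci_method: str = "wilson_pooled",
) -> pd.DataFrame:
    """Build a stratified agreement table (one row per stratum) with PPA/NPA
    and confidence intervals.

    ``ci_method`` is one of ``normal_per_sample`` (requires ``per_sample``
    counts), ``wald_pooled`` or ``wilson_pooled``.
    """
    rows = []
    for stratum, counts in strata_counts.items():
        row: dict = {
            "stratum": stratum,
            "tp": counts.tp,
            "fp": counts.fp,
            "fn": counts.fn,
            "tn": counts.tn,
            "ppa": ppa(counts),
            "npa": npa(counts),
            "ci_method": ci_method,
        }
        for which in ("ppa", "npa"):
            lo = hi = math.nan
            try:
                if ci_method == "normal_per_sample":
                    if per_sample is None:
                        raise ValueError(
                            "normal_per_sample CI requires per-sample counts"
                        )
                    metric = ppa if which == "ppa" else npa
                    lo, hi = ci_normal_per_sample(
                        [metric(c) for c in per_sample[stratum]], config
                    )
                else:
                    lo, hi = ci_pooled(
                        counts, which, ci_method.removesuffix("_pooled"), config
                    )
            except ValueError:
                pass  # undefined stratum: leave nan bounds
            row[f"{which}_ci_low"], row[f"{which}_ci_high"] = lo, hi
        rows.append(row)
    return pd.DataFrame(rows)
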