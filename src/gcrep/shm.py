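"""Somatic hypermutation levels, patterns and targeting per stratum.

SHM is quantified as the percentage of mutated positions of the aligned V
region.  The CDR3/junction is excluded (junction diversity is not SHM), as
are primer-masked FR1 positions and N positions — the denominator is the
aligned, unmasked, non-N V length.  Pattern fractions summarise the
processing of AID-induced U lesions: mutations at G:C versus A:T pairs,
transition fractions within each, hotspot-motif (RGYW/WRCY) targeting, and
replacement fractions in CDR versus framework.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .clones import FilterReport, stratum_of


class InsufficientDataError(ValueError):
    pass


class StratumExcludedError(ValueError):
    pass


@dataclass(frozen=True)
class MutationPattern:
    frac_at_GC: float
    frac_at_AT: float
    frac_transition_at_GC: float
    frac_transition_at_AT: float
    frac_in_RGYW: float
    frac_in_WRCY: float
    frac_replacement_CDR: float
    frac_replacement_FWR: float


@dataclass(frozen=True)
class MutationProfile:
    stratum: tuple  # (population, isotype)
    n_sequences: int
    shm_percent_median: float
    shm_percent_values: tuple[float, ...]
    pattern: MutationPattern | None  # None when the stratum has no mutations


def shm_percent(r, primer_mask: int = 0) -> float:
    """Percent mutated positions of the aligned V (CDR3 and mask excluded)."""
    denominator = r.v_valid_length - primer_mask
    if denominator <= 0:
        raise InsufficientDataError(
            f"read {r.read_id}: no countable V positions after masking"
        )
    n = sum(1 for m in r.mutations if m.position >= primer_mask)
    return 100.0 * n / denominator


def pooled_pattern(mutations) -> MutationPattern | None:
    """Pattern fractions pooled over a stratum's mutations; None if empty."""
    muts = list(mutations)
    if not muts:
        return None
    n = len(muts)
    gc = [m for m in muts if m.strand_class == "GC"]
    at = [m for m in muts if m.strand_class == "AT"]
    cdr = [m for m in muts if m.region.startswith("CDR")]
    fwr = [m for m in muts if m.region.startswith("FR")]

    def frac(sub, pool):
        return len(sub) / len(pool) if pool else math.nan

    return MutationPattern(
        frac_at_GC=len(gc) / n,
        frac_at_AT=len(at) / n,
        frac_transition_at_GC=frac([m for m in gc if m.transition], gc),
        frac_transition_at_AT=frac([m for m in at if m.transition], at),
        frac_in_RGYW=sum(m.at_rgyw for m in muts) / n,
        frac_in_WRCY=sum(m.at_wrcy for m in muts) / n,
        frac_replacement_CDR=frac([m for m in cdr if m.rs_class == "replacement"], cdr),
        frac_replacement_FWR=frac([m for m in fwr if m.rs_class == "replacement"], fwr),
    )


def population_shm_summary(rearrangements, filter_report: FilterReport | None = None,
                           primer_mask: int = 0) -> list[MutationProfile]:
    """Per-stratum SHM medians, full distributions and pooled patterns.

    Records are expected to come from the clone-collapse regime. Requesting
    a stratum that the filter report excludes raises StratumExcludedError.
    """
    by_stratum: dict[tuple, list] = {}
    for r in rearrangements:
        by_stratum.setdefault(stratum_of(r), []).append(r)
    profiles = []
    for st in sorted(by_stratum):
        if filter_report is not None and filter_report.is_excluded(st):
            raise StratumExcludedError(
                f"stratum {st} is excluded by the {filter_report.regime} filter report "
                f"(<{filter_report.min_sequences} sequences)"
            )
        records = by_stratum[st]
        values = tuple(shm_percent(r, primer_mask) for r in records)
        muts = [m for r in records for m in r.mutations if m.position >= primer_mask]
        profiles.append(
            MutationProfile(
                stratum=st, n_sequences=len(records),
                shm_percent_median=float(np.median(values)),
                shm_percent_values=values, pattern=pooled_pattern(muts),
            )
        )
    return profiles


@dataclass(frozen=True)
class TTestResult:
    t_statistic: float
    p_value: float
    direction: int  # sign(mean(CB) - mean(CC))


def compare_cb_cc(cb_values, cc_values, welch: bool = True) -> TTestResult:
    """Two-sided unpaired t-test on per-sequence SHM percentages.

    Welch (unequal variance) by default; ``welch=False`` gives the Student
    variant.  Direction is the sign of mean(CB) - mean(CC).
    """
    cb = np.asarray(list(cb_values), dtype=float)
    cc = np.asarray(list(cc_values), dtype=float)
    if len(cb) < 2 or len(cc) < 2:
        raise InsufficientDataError("both strata need >= 2 SHM values")
    res = stats.ttest_ind(cb, cc, equal_var=not welch)
    t = float(res.statistic)
    p = float(res.pvalue)
    if math.isnan(t):  # zero variance in both and equal means
        t, p = 0.0, 1.0
    return TTestResult(t_statistic=t, p_value=p,
                       direction=int(np.sign(cb.mean() - cc.mean())))
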