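"""Antigen-selection scoring from replacement/silent mutation distributions.

The neutral expectation is built by exhaustive enumeration: every possible
single-base substitution at every countable germline V position is weighted
by a targeting model (multiplicative hotspot weight inside RGYW/WRCY, an
optional transition bias), yielding (a) the expected fraction of mutations
falling in the CDRs and (b) the expected replacement fraction within CDR
and within framework.  Observed stratum mutation counts are then tested
against these expectations with an exact two-sided binomial test and a
Clopper-Pearson 95% interval; the selection score is the log odds ratio

    sigma = log( odds(observed fraction) / odds(expected fraction) )

which is 0 exactly under neutrality, positive under enrichment, and
antisymmetric around a 0.5 expectation.  CDR3 is
excluded throughout (no germline to enumerate), consistent with the SHM
denominator.  Expectations are aggregated across V genes by weighting each
sequence's gene-specific expectation by its mutation count, so heavily
mutated sequences dominate appropriately.

This is an explicit, fully testable reimplementation choice (enumeration +
exact binomial inference), not a reproduction of any published selection
framework.
"""
from __future__ import annotations

import math
from dataclasses import dataclass

from scipy import stats

from .reference import GermlineReference, ReferenceError, VGene, motif_positions
from .simulate import CODON_AA

_ALT = {b: tuple(x for x in "ACGT" if x != b) for b in "ACGT"}


@dataclass(frozen=True)
class NeutralExpectation:
    exp_cdr_frac: float  # expected fraction of mutations falling in CDR
    exp_r_frac: dict  # region ("CDR"/"FWR") -> expected replacement fraction


@dataclass(frozen=True)
class SelectionResult:
    stratum: tuple | None
    test: str  # "allocation" (CDR vs FWR placement) or "rs" (R vs S in region)
    region: str  # "CDR" | "FWR"
    obs_R: int  # for "allocation": mutations in CDR
    obs_S: int  # for "allocation": mutations in FWR
    exp_R_frac: float
    sigma: float
    ci_low: float
    ci_high: float
    p_value: float
    no_mutations: bool = False

    @property
    def obs_total(self) -> int:
        return self.obs_R + self.obs_S


def neutral_expectation(v_gene: VGene, hotspot_weight: float = 1.0,
                        transition_bias: float = 1.0,
                        primer_mask: int = 0) -> NeutralExpectation:
    """Enumerate all single-base substitutions of a germline V, weighted.

    Each substitution's weight is (hotspot_weight if the position is inside
    an RGYW/WRCY motif else 1) x (transition_bias if the substitution is a
    transition else 1).  Region labels come from the gene's IMGT-derived
    region map.
    """
    if not v_gene.regions:
        raise ReferenceError(f"V gene {v_gene.name}: region map missing")
    rgyw, wrcy = motif_positions(v_gene.seq)
    hot = rgyw | wrcy
    region_map = v_gene.region_map
    w_region = {"CDR": 0.0, "FWR": 0.0}
    w_repl = {"CDR": 0.0, "FWR": 0.0}
    seq = v_gene.seq
    for pos in range(primer_mask, len(seq)):
        base = seq[pos]
        if base == "N":
            continue
        region = "CDR" if str(region_map[pos]).startswith("CDR") else "FWR"
        pos_w = hotspot_weight if pos in hot else 1.0
        ci = pos // 3
        codon = seq[3 * ci : 3 * ci + 3]
        if len(codon) < 3 or "N" in codon:
            continue
        for to in _ALT[base]:
            w = pos_w * (transition_bias if {base, to} in ({"A", "G"}, {"C", "T"}) else 1.0)
            new_codon = codon[: pos % 3] + to + codon[pos % 3 + 1 :]
            repl = CODON_AA[codon] != CODON_AA[new_codon]
            w_region[region] += w
            if repl:
                w_repl[region] += w
    total = w_region["CDR"] + w_region["FWR"]
    return NeutralExpectation(
        exp_cdr_frac=w_region["CDR"] / total if total else math.nan,
        exp_r_frac={
            reg: (w_repl[reg] / w_region[reg] if w_region[reg] else math.nan)
            for reg in ("CDR", "FWR")
        },
    )


def binomial_selection_result(x: int, n: int, p0: float, stratum=None,
                              test: str = "rs", region: str = "CDR") -> SelectionResult:
    """Exact binomial test of x/n against p0 with the log-odds selection score.

    sigma = log( odds(x/n) / odds(p0) ): zero exactly at the expectation,
    antisymmetric around a 0.5 expectation, +/-inf at the boundaries.
    """
    if n == 0:
        return SelectionResult(stratum, test, region, 0, 0, p0,
                               math.nan, math.nan, math.nan, math.nan,
                               no_mutations=True)
    bt = stats.binomtest(x, n, p0)
    ci = bt.proportion_ci(confidence_level=0.95, method="exact")
    frac = x / n
    if frac <= 0:
        sigma = -math.inf
    elif frac >= 1:
        sigma = math.inf
    else:
        sigma = math.log(frac / (1 - frac)) - math.log(p0 / (1 - p0))
    return SelectionResult(stratum, test, region, x, n - x, p0, sigma,
                           float(ci.low), float(ci.high), float(bt.pvalue))


def selection_score(rearrangements, ref: GermlineReference,
                    hotspot_weight: float = 1.0, transition_bias: float = 1.0,
                    primer_mask: int = 0, stratum=None) -> list[SelectionResult]:
    """Selection results for one stratum's pooled mutations.

    Returns three results: the CDR-allocation test (observed CDR mutations
    vs expected CDR fraction) and the within-region R/S tests for CDR and
    FWR. Per-sequence expectations are aggregated weighted by each
    sequence's mutation count.
    """
    exp_cache: dict[str, NeutralExpectation] = {}

    def expectation(v_call):
        if v_call not in exp_cache:
            exp_cache[v_call] = neutral_expectation(
                ref.v_genes[v_call], hotspot_weight, transition_bias, primer_mask
            )
        return exp_cache[v_call]

    obs = {"CDR": {"R": 0, "S": 0}, "FWR": {"R": 0, "S": 0}}
    w_cdr = w_rcdr = w_rfwr = w_total = 0.0
    for r in rearrangements:
        muts = [m for m in r.mutations if m.position >= primer_mask]
        if not muts:
            continue
        e = expectation(r.v_call)
        m_i = len(muts)
        w_total += m_i
        w_cdr += m_i * e.exp_cdr_frac
        w_rcdr += m_i * e.exp_r_frac["CDR"]
        w_rfwr += m_i * e.exp_r_frac["FWR"]
        for m in muts:
            region = "CDR" if m.region.startswith("CDR") else "FWR"
            obs[region]["R" if m.rs_class == "replacement" else "S"] += 1

    n_cdr = obs["CDR"]["R"] + obs["CDR"]["S"]
    n_fwr = obs["FWR"]["R"] + obs["FWR"]["S"]
    n_all = n_cdr + n_fwr
    if w_total == 0:
        nan = math.nan
        return [
            SelectionResult(stratum, "allocation", "CDR", 0, 0, nan, nan, nan, nan, nan,
                            no_mutations=True),
            SelectionResult(stratum, "rs", "CDR", 0, 0, nan, nan, nan, nan, nan,
                            no_mutations=True),
            SelectionResult(stratum, "rs", "FWR", 0, 0, nan, nan, nan, nan, nan,
                            no_mutations=True),
        ]
    exp_cdr = w_cdr / w_total
    exp_r = {"CDR": w_rcdr / w_total, "FWR": w_rfwr / w_total}
    return [
        binomial_selection_result(n_cdr, n_all, exp_cdr, stratum, "allocation", "CDR"),
        binomial_selection_result(obs["CDR"]["R"], n_cdr, exp_r["CDR"], stratum, "rs", "CDR"),
        binomial_selection_result(obs["FWR"]["R"], n_fwr, exp_r["FWR"], stratum, "rs", "FWR"),
    ]
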