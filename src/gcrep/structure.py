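"""Clonality, cross-population clonal overlap, IGHG subclass distribution,
and per-clone shared/unique mutation reports.

Clonality is summarised per stratum by four standard repertoire metrics
(largest-clone fraction, expanded-clone fraction, Gini coefficient of clone
sizes, normalised Shannon evenness); a clonality plot uses expanded fraction
against evenness, which reproduces the qualitative corners "little
clonality" / "one very large clone" / "many small clones".

A clone counts as shared in a population if it also contains at least one
sequence from another population; a clone spanning three populations
contributes to all three numerators.  The subclass distal index is the
combined fraction of the distal subclasses (G2+G4 for IGHG, A2 for IGHA)
among assigned subclasses, following the proximal-to-distal locus order
G3 < G1 < G2 < G4.
"""
from __future__ import annotations

import math
import warnings
from collections import defaultdict
from dataclasses import dataclass

import numpy as np

from .clones import Clone, EmptyStratumError, stratum_of

GAMMA_SUBCLASSES = ("G3", "G1", "G2", "G4")  # proximal -> distal (locus order)
ALPHA_SUBCLASSES = ("A1", "A2")
DISTAL = {"G": ("G2", "G4"), "A": ("A2",)}


class ContractError(ValueError):
    pass


@dataclass(frozen=True)
class ClonalityPoint:
    stratum: tuple
    n_clones: int
    n_unique_sequences: int
    largest_clone_fraction: float
    expanded_fraction: float  # fraction of unique sequences in clones of size >= 2
    gini: float
    shannon_evenness: float


def gini_coefficient(sizes) -> float:
    x = np.asarray(list(sizes), dtype=float)
    if len(x) == 0 or x.sum() == 0:
        return 0.0
    diffs = np.abs(x[:, None] - x[None, :]).sum()
    return float(diffs / (2 * len(x) ** 2 * x.mean()))


def shannon_evenness(sizes) -> float:
    x = np.asarray(list(sizes), dtype=float)
    k = len(x)
    if k <= 1:
        return 0.0
    p = x / x.sum()
    h = -np.sum(p * np.log(p, where=p > 0, out=np.zeros_like(p)))
    return float(h / math.log(k))


def clonality_metrics(clones, stratum=None) -> ClonalityPoint:
    """Clonality metrics for one stratum (unique-sequence regime expected).

    Clone size is the number of distinct member sequences (restricted to the
    stratum when one is given); clones absent from the stratum are ignored.
    """
    sizes = []
    for c in clones:
        members = c.members if stratum is None else c.members_in(stratum)
        n = len({m.sequence for m in members})
        if n:
            sizes.append(n)
    if not sizes:
        raise EmptyStratumError(f"stratum {stratum}: no sequences")
    total = sum(sizes)
    return ClonalityPoint(
        stratum=stratum, n_clones=len(sizes), n_unique_sequences=total,
        largest_clone_fraction=max(sizes) / total,
        expanded_fraction=sum(s for s in sizes if s >= 2) / total,
        gini=gini_coefficient(sizes),
        shannon_evenness=shannon_evenness(sizes),
    )


@dataclass(frozen=True)
class OverlapResult:
    donor: str
    populations: tuple[str, ...]
    n_clones_in_population: dict
    n_shared: dict
    pct_shared: dict
    pairwise: dict  # (pop_a, pop_b) sorted pair -> clone count
    membership: dict  # frozenset of populations -> clone count


def cross_population_overlap(clones, donor: str = "") -> OverlapResult:
    """Per-population shared-clone percentages and the pairwise matrix.

    Requires clone grouping to have run jointly across the donor's
    populations. With a single population present, all percentages are 0
    and a warning is emitted.
    """
    pops = sorted({p for c in clones for p in c.populations_present})
    if len(pops) <= 1:
        warnings.warn("cross_population_overlap: input spans a single population; "
                      "all shared percentages are 0", stacklevel=2)
    n_in_pop: dict = defaultdict(int)
    n_shared: dict = defaultdict(int)
    pairwise: dict = defaultdict(int)
    membership: dict = defaultdict(int)
    for c in clones:
        present = c.populations_present
        membership[frozenset(present)] += 1
        for p in present:
            n_in_pop[p] += 1
            if len(present) > 1:
                n_shared[p] += 1
        ordered = sorted(present)
        for i, a in enumerate(ordered):
            for b in ordered[i + 1 :]:
                pairwise[(a, b)] += 1
    pct = {p: 100.0 * n_shared[p] / n_in_pop[p] for p in pops}
    return OverlapResult(
        donor=donor, populations=tuple(pops),
        n_clones_in_population={p: n_in_pop[p] for p in pops},
        n_shared={p: n_shared[p] for p in pops}, pct_shared=pct,
        pairwise=dict(pairwise), membership=dict(membership),
    )


@dataclass(frozen=True)
class SubclassDistribution:
    stratum: tuple | None
    isotype: str  # "G" or "A"
    counts: dict
    fractions: dict  # over assigned subclasses; sums to 1
    none_fraction: float  # fraction of records with no subclass call
    distal_index: float  # combined fraction of the distal subclasses
    empty: bool = False


def subclass_distribution(rearrangements, isotype: str = "G",
                          stratum=None) -> SubclassDistribution:
    """Subclass usage among records of one isotype class (clone-collapse regime)."""
    allowed = GAMMA_SUBCLASSES if isotype == "G" else ALPHA_SUBCLASSES
    records = [r for r in rearrangements if r.isotype == isotype]
    counts = {s: 0 for s in allowed}
    n_none = 0
    for r in records:
        if r.subclass in counts:
            counts[r.subclass] += 1
        else:
            n_none += 1
    assigned = sum(counts.values())
    if assigned == 0:
        return SubclassDistribution(stratum, isotype, counts, {s: math.nan for s in allowed},
                                    n_none / len(records) if records else math.nan,
                                    math.nan, empty=True)
    fractions = {s: counts[s] / assigned for s in allowed}
    distal = sum(fractions[s] for s in DISTAL[isotype])
    return SubclassDistribution(stratum, isotype, counts, fractions,
                                n_none / len(records), distal)


@dataclass(frozen=True)
class CloneMutationReport:
    clone_id: str
    member_ids: tuple[str, ...]
    member_labels: dict  # read_id -> (population, subclass)
    matrix: dict  # read_id -> {position: "R" | "S"}
    shared_mutations: frozenset
    partial_mutations: frozenset
    unique_mutations: frozenset
    cdr_positions: frozenset
    v_length: int

    def render_text(self, width: int = 100) -> str:
        """Plain-text alignment: R/S markers per member, CDRs marked with ^."""
        lines = [f"clone {self.clone_id}: {len(self.member_ids)} members, "
                 f"{len(self.shared_mutations)} shared / {len(self.partial_mutations)} "
                 f"partial / {len(self.unique_mutations)} unique mutated positions"]
        label_w = max((len(m) for m in self.member_ids), default=10) + 2
        for start in range(0, self.v_length, width):
            end = min(start + width, self.v_length)
            ruler = "".join("^" if p in self.cdr_positions else "." for p in range(start, end))
            lines.append(f"{'CDR'.ljust(label_w)}{ruler}")
            for rid in self.member_ids:
                row = self.matrix[rid]
                track = "".join(row.get(p, "-") for p in range(start, end))
                pop, sub = self.member_labels[rid]
                lines.append(f"{f'{pop}/{sub}'.ljust(label_w)}{track}")
            lines.append("")
        return "\n".join(lines)


def clone_mutation_report(clone: Clone, ref) -> CloneMutationReport:
    """Shared/partial/unique mutation structure of one clone.

    All members must be aligned to the same germline V; mutated positions
    are classified per member as replacement or silent, and positions are
    partitioned into shared (all members), partial (>= 2 but not all) and
    unique (exactly one member) sets.
    """
    v_genes = {m.v_gene for m in clone.members}
    if len(v_genes) != 1:
        raise ContractError(
            f"clone {clone.clone_id}: members carry different v_call ({sorted(v_genes)})"
        )
    v = ref.v_genes[clone.members[0].v_call]
    cdr = frozenset(
        p for region, (s, e) in v.regions.items() if region.startswith("CDR")
        for p in range(s, e)
    )
    members = sorted(clone.members, key=lambda m: m.read_id)
    matrix = {
        m.read_id: {mu.position: ("R" if mu.rs_class == "replacement" else "S")
                    for mu in m.mutations}
        for m in members
    }
    pos_counts: dict = defaultdict(int)
    for row in matrix.values():
        for p in row:
            pos_counts[p] += 1
    n = len(members)
    shared = frozenset(p for p, c in pos_counts.items() if c == n)
    unique = frozenset(p for p, c in pos_counts.items() if c == 1) - (shared if n == 1 else frozenset())
    partial = frozenset(pos_counts) - shared - unique
    return CloneMutationReport(
        clone_id=clone.clone_id, member_ids=tuple(m.read_id for m in members),
        member_labels={m.read_id: (m.population, m.subclass) for m in members},
        matrix=matrix, shared_mutations=shared, partial_mutations=partial,
        unique_mutations=unique, cdr_positions=cdr, v_length=len(v.seq),
    )
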