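"""Clone inference and the two filtering regimes.

A clone is operationally defined as: same V gene and J gene (gene level —
allele calls are unstable under SHM), same junction length, and junction
nucleotide identity >= a threshold (default 0.85, the common AIRR
convention) under single-linkage clustering.  Clustering is performed
jointly across all populations of one donor, which is what makes the
cross-population overlap analysis meaningful.

Two regimes mirror the two published analyses:

* CLONE_COLLAPSE — one representative per clone per population x isotype
  stratum, to preclude skewing of SHM/selection/subclass summaries by large
  clones.
* UNIQUE — collapse identical sequences (summing duplicate counts, removing
  amplification bias) and suppress unsupported singletons as a documented
  stand-in for the original error-removal recipe.

Strata whose filtered output falls below ``min_sequences`` (default 45) are
excluded from all downstream summaries.
"""
from __future__ import annotations

import logging
from collections import Counter, defaultdict
from dataclasses import dataclass, replace

import numpy as np

from .annotate import Rearrangement

logger = logging.getLogger(__name__)

CLONE_COLLAPSE = "CLONE_COLLAPSE"
UNIQUE = "UNIQUE"
DEFAULT_MIN_SEQUENCES = 45


class EmptyStratumError(ValueError):
    pass


def stratum_of(r: Rearrangement) -> tuple[str, str]:
    """(population, isotype class) stratum key of a record."""
    return (r.population, r.isotype if r.isotype else "none")


@dataclass
class Clone:
    clone_id: str
    v_gene: str
    j_gene: str
    junction_length: int
    members: list

    @property
    def populations_present(self) -> frozenset[str]:
        return frozenset(m.population for m in self.members)

    @property
    def size_unique(self) -> int:
        return len({m.sequence for m in self.members})

    def members_in(self, stratum) -> list:
        return [m for m in self.members if stratum_of(m) == stratum]


@dataclass(frozen=True)
class StratumStatus:
    reads_in: int
    reads_out: int
    excluded: bool
    exclusion_reason: str = ""


@dataclass
class FilterReport:
    regime: str
    min_sequences: int
    rows: dict

    def is_excluded(self, stratum) -> bool:
        status = self.rows.get(stratum)
        return status.excluded if status is not None else False

    def included_strata(self):
        return [s for s, st in sorted(self.rows.items()) if not st.excluded]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "regime": self.regime, "population": s[0], "isotype": s[1],
                    "reads_in": st.reads_in, "reads_out": st.reads_out,
                    "excluded": st.excluded, "exclusion_reason": st.exclusion_reason,
                }
                for s, st in sorted(self.rows.items())
            ]
        )


class _UnionFind:
    def __init__(self, n):
        self.parent = list(range(n))

    def find(self, i):
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i, j):
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def _junction_linked(a: str, b: str, threshold: float) -> bool:
    mism = sum(x != y for x, y in zip(a, b))
    return 1.0 - mism / len(a) >= threshold


def group_clones(rearrangements, junction_identity_threshold: float = 0.85) -> list[Clone]:
    """Partition records into clones (joint across populations).

    Partition by (V gene, J gene, junction length), then single-linkage on
    junction Hamming identity >= the threshold.  Records without a junction
    are skipped and logged.  Clone ids are stable: groups are ordered by
    their smallest member read_id.
    """
    usable, skipped = [], 0
    for r in rearrangements:
        if r.junction:
            usable.append(r)
        else:
            skipped += 1
    if skipped:
        logger.info("group_clones: skipped %d records without junction", skipped)
    partitions: dict[tuple, list] = defaultdict(list)
    for r in usable:
        partitions[(r.v_gene, r.j_gene, len(r.junction))].append(r)
    groups = []
    for key in sorted(partitions):
        part = sorted(partitions[key], key=lambda r: r.read_id)
        n = len(part)
        uf = _UnionFind(n)
        juncs = [r.junction for r in part]
        for i in range(n):
            for j in range(i + 1, n):
                if _junction_linked(juncs[i], juncs[j], junction_identity_threshold):
                    uf.union(i, j)
        by_root = defaultdict(list)
        for i in range(n):
            by_root[uf.find(i)].append(part[i])
        for members in by_root.values():
            groups.append((key, sorted(members, key=lambda r: r.read_id)))
    groups.sort(key=lambda g: g[1][0].read_id)
    clones = []
    for idx, ((vg, jg, jl), members) in enumerate(groups):
        clones.append(Clone(f"clone_{idx + 1:05d}", vg, jg, jl, members))
    return clones


def _consensus(seqs: list[str]) -> str:
    n = min(len(s) for s in seqs)
    out = []
    for i in range(n):
        counts = Counter(s[i] for s in seqs)
        out.append(max(sorted(counts), key=lambda b: counts[b]))
    return "".join(out)


def collapse_one_per_clone(clones, selector: str = "closest-to-consensus") -> list[Rearrangement]:
    """One representative per clone per population x isotype stratum.

    Default representative is the member closest (Hamming) to the stratum's
    per-position majority consensus, the choice that minimises
    sequencing-error bias; ties broken by highest duplicate_count then
    smallest read_id.  ``selector`` may also be "first" or "most-mutated"
    for sensitivity analysis.
    """
    out = []
    for clone in clones:
        strata = sorted({stratum_of(m) for m in clone.members})
        for st in strata:
            members = clone.members_in(st)
            if not members:
                continue
            if selector == "first":
                rep = min(members, key=lambda r: r.read_id)
            elif selector == "most-mutated":
                rep = sorted(members, key=lambda r: (-len(r.mutations), r.read_id))[0]
            elif selector == "closest-to-consensus":
                cons = _consensus([m.sequence for m in members])
                def dist(r):
                    return sum(a != b for a, b in zip(r.sequence, cons))
                rep = sorted(members, key=lambda r: (dist(r), -r.duplicate_count, r.read_id))[0]
            else:
                raise ValueError(f"unknown selector {selector!r}")
            out.append(rep)
    return out


def unique_sequence_filter(rearrangements, junction_identity_threshold: float = 0.85,
                           absorb_radius: int = 1) -> list[Rearrangement]:
    """Collapse to unique sequences and suppress likely sequencing errors.

    Within each population x isotype stratum identical nucleotide sequences
    are merged into one record (duplicate counts summed).  Records with a
    summed duplicate_count of 1 are then treated as unsupported: they are
    removed if their full sequence lies within ``absorb_radius`` mismatches
    of a supported (count >= 2) record of the same stratum and length (a
    likely error copy), or if they are not within the clone-linkage
    threshold of any supported record at all (an unsupported isolate);
    singletons clonally linked to supported records are retained as genuine
    rare variants.  Idempotent.
    """
    merged: dict[tuple, Rearrangement] = {}
    for r in sorted(rearrangements, key=lambda r: r.read_id):
        key = (stratum_of(r), r.sequence)
        if key in merged:
            merged[key] = replace(merged[key],
                                  duplicate_count=merged[key].duplicate_count + r.duplicate_count)
        else:
            merged[key] = r
    records = sorted(merged.values(), key=lambda r: r.read_id)
    supported = [r for r in records if r.duplicate_count >= 2]
    sup_by_stratum_len = defaultdict(list)
    for r in supported:
        sup_by_stratum_len[(stratum_of(r), len(r.sequence))].append(r)
    sup_junctions = defaultdict(list)
    for r in supported:
        if r.junction:
            sup_junctions[(r.v_gene, r.j_gene, len(r.junction))].append(r.junction)

    def near_supported(r):
        for s in sup_by_stratum_len[(stratum_of(r), len(r.sequence))]:
            if s.read_id == r.read_id:
                continue
            mism = 0
            for a, b in zip(r.sequence, s.sequence):
                if a != b:
                    mism += 1
                    if mism > absorb_radius:
                        break
            else:
                return True
            if mism <= absorb_radius:
                return True
        return False

    def clone_linked(r):
        if not r.junction:
            return False
        for j in sup_junctions[(r.v_gene, r.j_gene, len(r.junction))]:
            if _junction_linked(r.junction, j, junction_identity_threshold):
                return True
        return False

    out = []
    for r in records:
        if r.duplicate_count >= 2:
            out.append(r)
        elif near_supported(r):
            continue  # absorbed: likely an error copy of a supported record
        elif clone_linked(r):
            out.append(r)
    return out


def apply_population_threshold(counts_in: dict, counts_out: dict, regime: str,
                               min_sequences: int = DEFAULT_MIN_SEQUENCES) -> FilterReport:
    """Flag strata whose post-filter count falls below ``min_sequences``.

    ``counts_in`` / ``counts_out`` map (population, isotype) strata to record
    counts before and after the regime's filtering. Downstream summary
    operations refuse excluded strata.
    """
    rows = {}
    for st in sorted(set(counts_in) | set(counts_out)):
        n_in = int(counts_in.get(st, 0))
        n_out = int(counts_out.get(st, 0))
        excluded = n_out < min_sequences
        reason = ""
        if excluded:
            reason = "empty" if n_out == 0 else f"<{min_sequences} sequences"
        rows[st] = StratumStatus(n_in, n_out, excluded, reason)
        if excluded:
            logger.info("stratum %s excluded under %s: %s (%d sequences)",
                        st, regime, reason, n_out)
    return FilterReport(regime=regime, min_sequences=min_sequences, rows=rows)


def stratum_counts(rearrangements) -> dict:
    counts: dict = defaultdict(int)
    for r in rearrangements:
        counts[stratum_of(r)] += 1
    return dict(counts)
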