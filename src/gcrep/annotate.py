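"""Read annotation against the germline reference.

Self-contained ungapped-seed aligner (no external annotation service): V and
J genes are located by exact k-mer seeds voting for a diagonal, the best
diagonal is extended ungapped over the full overlap, and percent identity is
computed over non-N positions.  Indels are a non-goal (the simulator emits
substitutions only and the amplicon design is substitution-dominated), so
ungapped alignment is exact for the data this pipeline targets; reads that
fail the identity floor are reported unassignable rather than force-fitted.

Mutation calling compares the aligned V to its germline gene position by
position.  Replacement/silent classification evaluates each mutated codon
against the germline codon with the *other* read positions held at the read
state, in read order — a deterministic convention for codons carrying more
than one mutation.  CDR3/junction positions are never counted as SHM.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .reference import GermlineReference, VGene
from .simulate import CODON_AA

logger = logging.getLogger(__name__)

POPULATION_LABELS = ("naive", "CB", "CC", "mem", "PB", "NE", "other")


class FrameError(ValueError):
    """Reading frame could not be established for a read."""


@dataclass(frozen=True)
class Mutation:
    position: int  # 0-based on the ungapped germline V
    from_base: str
    to_base: str
    region: str  # FR1/CDR1/FR2/CDR2/FR3
    rs_class: str  # "replacement" | "silent"
    at_rgyw: bool
    at_wrcy: bool
    strand_class: str  # "GC" | "AT" (germline base pair)
    transition: bool


@dataclass(frozen=True)
class Rearrangement:
    read_id: str
    sequence: str
    v_call: str
    j_call: str
    v_identity: float
    junction: str
    mutations: tuple[Mutation, ...]
    isotype: str | None  # class level: M, G, A
    subclass: str  # G1..G4, A1, A2, M or "none"
    sample_id: str = ""
    population: str = "other"
    compartment: str = "SLO"
    duplicate_count: int = 1
    v_start: int = 0  # start of the aligned V in the read
    v_germline_length: int = 0  # aligned germline V length
    v_valid_length: int = 0  # non-N aligned positions (identity denominator)
    productive: bool = True
    extras: tuple = ()  # unknown AIRR columns, preserved for round-trip

    @property
    def v_gene(self) -> str:
        return self.v_call.split("*", 1)[0]

    @property
    def j_gene(self) -> str:
        return self.j_call.split("*", 1)[0]


@dataclass
class AnnotationLog:
    n_input: int = 0
    n_assigned: int = 0
    n_unassignable: int = 0
    n_frame_error: int = 0
    unassignable_ids: list = field(default_factory=list)


def _seed_align(read: str, gene: str, k: int, step: int):
    """Best ungapped placement of `gene` inside `read` by k-mer diagonal voting.

    Returns (diag, matches, valid, identity, g_start, g_end) or None; `diag`
    is the read position of germline position 0 (may be negative).
    """
    index: dict[str, list[int]] = {}
    for i in range(len(read) - k + 1):
        index.setdefault(read[i : i + k], []).append(i)
    votes: dict[int, int] = {}
    for s in range(0, len(gene) - k + 1, step):
        for rp in index.get(gene[s : s + k], ()):
            d = rp - s
            votes[d] = votes.get(d, 0) + 1
    if not votes:
        return None
    diag = max(sorted(votes), key=lambda d: votes[d])
    g0 = max(0, -diag)
    g1 = min(len(gene), len(read) - diag)
    if g1 <= g0:
        return None
    a = np.frombuffer(read[diag + g0 : diag + g1].encode(), dtype="S1")
    b = np.frombuffer(gene[g0:g1].encode(), dtype="S1")
    valid = (a != b"N") & (b != b"N")
    matches = int(((a == b) & valid).sum())
    n_valid = int(valid.sum())
    if n_valid == 0:
        return None
    return diag, matches, n_valid, matches / n_valid, g0, g1


def assign_vj(read: str, ref: GermlineReference, min_identity: float = 0.60,
              min_overlap: int = 100):
    """Best V and J calls for a read; None if no V passes the identity floor.

    Ties on alignment score are broken by lexicographically smallest gene
    name (genes are scanned in sorted order and only strictly better scores
    replace the incumbent).
    """
    if len(read) < 150:
        return None
    best = None
    for name in sorted(ref.v_genes):
        res = _seed_align(read, ref.v_genes[name].seq, k=12, step=6)
        if res is None:
            continue
        diag, matches, n_valid, ident, g0, g1 = res
        if ident < min_identity or (g1 - g0) < min_overlap:
            continue
        if best is None or matches > best["score"]:
            best = {"v_call": name, "score": matches, "v_identity": ident,
                    "diag": diag, "g_start": g0, "g_end": g1}
    if best is None:
        return None
    v_end_read = best["diag"] + best["g_end"]
    tail_from = max(0, v_end_read - 6)
    tail = read[tail_from:]
    best_j = None
    for name in sorted(ref.j_genes):
        res = _seed_align(tail, ref.j_genes[name].seq, k=8, step=4)
        if res is None:
            continue
        diag, matches, n_valid, ident, g0, g1 = res
        if ident < 0.8 or (g1 - g0) < 18:
            continue
        if best_j is None or matches > best_j["score"]:
            best_j = {"j_call": name, "score": matches,
                      "j_start_read": tail_from + diag, "g_end": g1}
    best["j_call"] = best_j["j_call"] if best_j else ""
    best["j_start_read"] = best_j["j_start_read"] if best_j else None
    best["j_end_read"] = (best_j["j_start_read"] + best_j["g_end"]) if best_j else None
    return best


def call_mutations(read: str, v_offset: int, v_gene: VGene, g_start: int = 0,
                   g_end: int | None = None) -> tuple[tuple[Mutation, ...], int]:
    """All point mutations of the aligned V; returns (mutations, valid length).

    The junction is outside the aligned V by construction and never counted.
    N positions (read or germline) are skipped and excluded from the valid
    (identity-denominator) length.
    """
    g_end = len(v_gene.seq) if g_end is None else g_end
    if g_end - g_start < 3:
        raise FrameError("aligned V region too short to establish reading frame")
    rgyw, wrcy = v_gene.hotspot_sets
    region_map = v_gene.region_map
    muts = []
    n_valid = 0
    for g in range(g_start, g_end):
        rpos = v_offset + g
        if rpos < 0 or rpos >= len(read):
            continue
        gb, rb = v_gene.seq[g], read[rpos]
        if gb == "N" or rb == "N":
            continue
        n_valid += 1
        if gb == rb:
            continue
        ci = g // 3
        read_codon = "".join(
            read[v_offset + 3 * ci + o] if 0 <= v_offset + 3 * ci + o < len(read) else
            v_gene.seq[3 * ci + o]
            for o in range(3)
        )
        before = read_codon[: g % 3] + gb + read_codon[g % 3 + 1 :]
        if "N" in before or "N" in read_codon:
            rs = "silent"
        else:
            rs = "replacement" if CODON_AA[before] != CODON_AA[read_codon] else "silent"
        muts.append(
            Mutation(
                position=g, from_base=gb, to_base=rb, region=str(region_map[g]),
                rs_class=rs, at_rgyw=g in rgyw, at_wrcy=g in wrcy,
                strand_class="GC" if gb in "GC" else "AT",
                transition={gb, rb} in ({"A", "G"}, {"C", "T"}),
            )
        )
    return tuple(muts), n_valid


def assign_isotype_subclass(constant_segment: str, ref: GermlineReference,
                            min_overlap: int = 20, margin: int = 2,
                            fallback_isotype: str | None = None):
    """Isotype/subclass from the read's 3' constant segment.

    The subclass is the CH1 entry with fewest mismatches over the overlap,
    assigned only if it beats the runner-up by >= ``margin`` mismatches;
    otherwise subclass is "none" and the isotype comes from the class-level
    best (or the provided metadata fallback).
    """
    scores = {}
    for sub, c in sorted(ref.c_segments.items()):
        n = min(len(constant_segment), len(c.seq))
        if n < min_overlap:
            continue
        mism = sum(a != b for a, b in zip(constant_segment[:n], c.seq[:n]) if a != "N" and b != "N")
        scores[sub] = mism
    if not scores:
        return fallback_isotype, "none"
    ranked = sorted(scores.items(), key=lambda kv: (kv[1], kv[0]))
    best_sub, best_m = ranked[0]
    if len(ranked) == 1 or ranked[1][1] - best_m >= margin:
        return best_sub[0], best_sub
    by_class: dict[str, int] = {}
    for sub, m in scores.items():
        cls = sub[0]
        by_class[cls] = min(m, by_class.get(cls, np.inf))
    cranked = sorted(by_class.items(), key=lambda kv: (kv[1], kv[0]))
    if len(cranked) == 1 or cranked[1][1] - cranked[0][1] >= margin:
        return cranked[0][0], "none"
    return fallback_isotype, "none"


def annotate_read(read_id: str, sequence: str, ref: GermlineReference,
                  sample_id: str = "", population: str = "other",
                  compartment: str = "SLO", isotype_primer: str | None = None,
                  min_identity: float = 0.60, min_overlap: int = 100):
    """Annotate one read; returns a Rearrangement or None if unassignable."""
    vj = assign_vj(sequence, ref, min_identity=min_identity, min_overlap=min_overlap)
    if vj is None:
        return None
    v_gene = ref.v_genes[vj["v_call"]]
    muts, n_valid = call_mutations(sequence, vj["diag"], v_gene,
                                   g_start=vj["g_start"], g_end=vj["g_end"])
    v_identity = 1.0 - len(muts) / n_valid if n_valid else 0.0
    v_end_read = vj["diag"] + vj["g_end"]
    if vj["j_start_read"] is not None:
        junction = sequence[max(0, v_end_read - 3) : vj["j_start_read"] + 3]
        tail = sequence[vj["j_end_read"] :]
    else:
        junction = ""
        tail = ""
    isotype, subclass = assign_isotype_subclass(tail, ref, fallback_isotype=isotype_primer)
    return Rearrangement(
        read_id=read_id, sequence=sequence, v_call=vj["v_call"], j_call=vj["j_call"],
        v_identity=v_identity, junction=junction, mutations=muts, isotype=isotype,
        subclass=subclass, sample_id=sample_id, population=population,
        compartment=compartment, v_start=vj["diag"], v_germline_length=vj["g_end"] - vj["g_start"],
        v_valid_length=n_valid, productive=(len(junction) % 3 == 0),
    )


def annotate_reads(reads, ref: GermlineReference, min_identity: float = 0.60,
                   min_overlap: int = 100):
    """Annotate simulator reads (or any objects with read_id/sequence/metadata).

    Returns (rearrangements, AnnotationLog). Unassignable and frame-failing
    reads are excluded and logged.
    """
    out, log = [], AnnotationLog()
    for r in reads:
        log.n_input += 1
        try:
            ann = annotate_read(
                r.read_id, r.sequence, ref, sample_id=getattr(r, "sample_id", ""),
                population=getattr(r, "population", "other"),
                compartment=getattr(r, "compartment", "SLO"),
                isotype_primer=getattr(r, "isotype_primer", None),
                min_identity=min_identity, min_overlap=min_overlap,
            )
        except FrameError:
            log.n_frame_error += 1
            continue
        if ann is None:
            log.n_unassignable += 1
            log.unassignable_ids.append(r.read_id)
            continue
        log.n_assigned += 1
        out.append(ann)
    logger.info("annotate: %d in, %d assigned, %d unassignable, %d frame errors",
                log.n_input, log.n_assigned, log.n_unassignable, log.n_frame_error)
    return out, log
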