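"""Synthetic germinal-center repertoire generator with full ground truth.

The generative model is a branching B-cell lineage per clone: each division
adds a Poisson number of candidate point mutations to the V segment, with
positions weighted uniformly except for a multiplicative ``hotspot_weight``
inside RGYW/WRCY motifs of the clone's germline V, and an acceptance step
that biases CDR replacement mutations by the selection coefficient
``selection_s``.  Isotype state follows a per-division transition matrix
over the IGHC locus order (M, G3, G1, A1, G2, G4, A2); switching is
irreversible (upper-triangular matrix).  Sorted populations are sampling
labels with a per-population mean division count; populations with mean 0
(naive) are drawn as independent unmutated founders.  Emitted molecules are
PCR-duplicated and per-base sequencing error is applied, with ground truth
recording which differences are errors and which are true SHM.

Mechanistic GC dynamics (affinity landscapes, Tfh help, spatial structure,
indels) are out of scope; see the methods note for what the generator does
and does not emulate.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from Bio.Data import CodonTable

from .reference import ISOTYPES, GermlineReference, ReferenceError, builtin_reference, motif_positions

_t = CodonTable.unambiguous_dna_by_id[1]
CODON_AA = dict(_t.forward_table)
for _s in _t.stop_codons:
    CODON_AA[_s] = "*"

_BASES = "ACGT"
_ALT = {b: tuple(x for x in _BASES if x != b) for b in _BASES}

POPULATIONS = ("naive", "CB", "CC", "mem", "PB")
MIN_FOUNDER_V = 250  # nt


class ConfigError(ValueError):
    """A simulation parameter violates its contract (message names the field)."""


class InputError(ValueError):
    pass


@dataclass(frozen=True)
class PopulationPlan:
    """Target molecule count and mean GC division count for one population."""

    n_molecules: int
    mean_divisions: float


def default_csr_matrix(switch_rate: float = 0.08) -> np.ndarray:
    """Per-division isotype transition matrix over the IGHC locus order.

    Each state keeps most of its mass; ``switch_rate`` is the per-division
    probability of switching out of IgM, distributed over downstream states
    with proximal classes favoured. Already-switched states switch onward at
    a quarter of that rate. Upper-triangular by construction.
    """
    n = len(ISOTYPES)
    m = np.zeros((n, n))
    downstream_weight = {"G3": 0.25, "G1": 0.40, "A1": 0.10, "G2": 0.15, "G4": 0.05, "A2": 0.05}
    for i, iso in enumerate(ISOTYPES):
        rate = switch_rate if iso == "M" else switch_rate / 4
        targets = ISOTYPES[i + 1 :]
        if not targets:
            m[i, i] = 1.0
            continue
        w = np.array([downstream_weight[t] for t in targets])
        w = w / w.sum()
        m[i, i + 1 :] = rate * w
        m[i, i] = 1.0 - rate
    return m


def stepwise_csr_matrix(step_prob: float = 0.15) -> np.ndarray:
    """Transition matrix with mass only on the next distal state (and self)."""
    n = len(ISOTYPES)
    m = np.eye(n)
    for i in range(n - 1):
        m[i, i] = 1.0 - step_prob
        m[i, i + 1] = step_prob
    return m


def default_population_plan() -> dict[str, PopulationPlan]:
    return {
        "naive": PopulationPlan(150, 0.0),
        "CB": PopulationPlan(300, 10.0),
        "CC": PopulationPlan(300, 10.0),
        "mem": PopulationPlan(200, 8.0),
        "PB": PopulationPlan(200, 10.0),
    }


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic repertoire; defaults are the study conditions.

    ``mu`` is the expected number of candidate mutations per sequence per
    division; if ``mu_per_site`` is set it overrides ``mu`` with a per-site
    per-division rate (candidate count Poisson(mu_per_site * V length)).
    """

    n_clones: int = 200
    clone_size_law: str = "power_law"  # or "uniform"
    alpha: float = 2.5
    mu: float = 1.5
    mu_per_site: float | None = None
    hotspot_weight: float = 3.0
    selection_s: float = 0.5
    csr_matrix: np.ndarray = field(default_factory=default_csr_matrix)
    population_plan: dict[str, PopulationPlan] = field(default_factory=default_population_plan)
    clone_span_prob: float = 0.3
    span_populations: tuple[str, ...] | None = None  # None: all GC populations
    divisions_law: str = "poisson"  # per-cell division count: "poisson" | "fixed"
    pcr_dup_law: tuple[str, float] = ("geometric", 3.0)
    seq_error_rate: float = 0.002
    seed: int = 0

    def validate(self) -> None:
        if not (isinstance(self.n_clones, (int, np.integer)) and self.n_clones > 0):
            raise ConfigError("n_clones: must be a positive integer")
        if self.clone_size_law not in ("uniform", "power_law"):
            raise ConfigError("clone_size_law: must be 'uniform' or 'power_law'")
        if self.clone_size_law == "power_law" and not self.alpha > 1:
            raise ConfigError("alpha: must be > 1 for power_law clone sizes")
        if self.mu < 0:
            raise ConfigError("mu: must be >= 0")
        if self.mu_per_site is not None and self.mu_per_site < 0:
            raise ConfigError("mu_per_site: must be >= 0")
        if self.hotspot_weight < 1:
            raise ConfigError("hotspot_weight: must be >= 1")
        m = np.asarray(self.csr_matrix, dtype=float)
        if m.shape != (len(ISOTYPES), len(ISOTYPES)):
            raise ConfigError("csr_matrix: must be 7x7 over the IGHC locus order")
        if (m < 0).any() or (m > 1).any():
            raise ConfigError("csr_matrix: probabilities must be in [0, 1]")
        if not np.allclose(m.sum(axis=1), 1.0):
            raise ConfigError("csr_matrix: rows must sum to 1")
        if not np.allclose(m, np.triu(m)):
            raise ConfigError("csr_matrix: must be upper-triangular (switching is irreversible)")
        for pop, plan in self.population_plan.items():
            if plan.n_molecules < 0:
                raise ConfigError(f"population_plan[{pop}]: n_molecules must be >= 0")
            if plan.mean_divisions < 0:
                raise ConfigError(f"population_plan[{pop}]: mean_divisions must be >= 0")
        if not 0 <= self.clone_span_prob <= 1:
            raise ConfigError("clone_span_prob: must be in [0, 1]")
        if self.span_populations is not None:
            unknown = set(self.span_populations) - set(self.population_plan)
            if unknown:
                raise ConfigError(f"span_populations: unknown populations {sorted(unknown)}")
        if self.divisions_law not in ("poisson", "fixed"):
            raise ConfigError("divisions_law: must be 'poisson' or 'fixed'")
        law, mean = self.pcr_dup_law
        if law not in ("fixed", "geometric"):
            raise ConfigError("pcr_dup_law: law must be 'fixed' or 'geometric'")
        if mean < 1:
            raise ConfigError("pcr_dup_law: mean must be >= 1")
        if not 0 <= self.seq_error_rate <= 0.05:
            raise ConfigError("seq_error_rate: must be in [0, 0.05]")
        if not isinstance(self.seed, (int, np.integer)):
            raise ConfigError("seed: must be an integer")


@dataclass(frozen=True)
class LineageNode:
    node_id: int
    parent: int | None
    depth: int
    isotype: str
    branch_mutations: tuple[tuple[int, str, str], ...]
    v_seq: str


@dataclass(frozen=True)
class CloneTruth:
    clone_id: int
    v_call: str
    j_call: str
    junction: str
    n_insert: str
    founder_v: str
    nodes: dict[int, LineageNode]

    def path_to_root(self, node_id: int) -> list[int]:
        path = [node_id]
        while self.nodes[path[-1]].parent is not None:
            path.append(self.nodes[path[-1]].parent)
        return path

    def mrca(self, node_ids) -> int:
        """Deepest node ancestral to (or equal to) every given node."""
        common = None
        for nid in node_ids:
            anc = set(self.path_to_root(nid))
            common = anc if common is None else common & anc
        return max(common, key=lambda n: self.nodes[n].depth)

    def member_mutated_positions(self, node_id: int) -> frozenset[int]:
        seq = self.nodes[node_id].v_seq
        return frozenset(i for i, (a, b) in enumerate(zip(self.founder_v, seq)) if a != b)

    def trunk_positions(self, node_ids) -> frozenset[int]:
        """Positions mutated in the sampled members' MRCA relative to the founder."""
        return self.member_mutated_positions(self.mrca(node_ids))

    def shared_partial_unique(self, node_ids) -> tuple[frozenset, frozenset, frozenset]:
        """Shared / partial / unique mutated-position sets across sampled members."""
        sets = [self.member_mutated_positions(n) for n in node_ids]
        allpos = frozenset().union(*sets) if sets else frozenset()
        counts = {p: sum(p in s for s in sets) for p in allpos}
        shared = frozenset(p for p, c in counts.items() if c == len(sets))
        unique = frozenset(p for p, c in counts.items() if c == 1)
        if len(sets) == 1:
            # a single member's mutations are both "in all" and "in exactly one";
            # report them as shared, matching the report-side convention
            unique = frozenset()
        partial = allpos - shared - unique
        return shared, partial, unique


@dataclass(frozen=True)
class Molecule:
    molecule_id: int
    clone_id: int
    node_id: int
    population: str
    isotype: str  # true subclass-level state, e.g. "G1"
    sequence: str  # full transcript: mutated V + N-insert + J + CH1
    v_length: int
    true_mutations: tuple[tuple[int, str, str], ...]  # founder-vs-cell differences
    n_mutation_events: int = 0  # accepted mutation events along the lineage path


def _path(nodes, node_id):
    path = [node_id]
    while nodes[path[-1]].parent is not None:
        path.append(nodes[path[-1]].parent)
    return path


@dataclass(frozen=True)
class SimRead:
    read_id: str
    sequence: str
    sample_id: str
    population: str
    compartment: str
    isotype_primer: str  # class-level (M/G/A), as a primer would know it
    molecule_id: int


@dataclass(frozen=True)
class ReadTruth:
    read_id: str
    molecule_id: int
    clone_id: int
    node_id: int
    population: str
    isotype: str
    true_mutations: tuple[tuple[int, str, str], ...]
    error_positions: tuple[int, ...]


@dataclass(frozen=True)
class GroundTruth:
    reads: dict[str, ReadTruth]
    clones: dict[int, CloneTruth]
    molecules: dict[int, Molecule]


class Lineage:
    """Mutable branching lineage over one clone founder."""

    def __init__(self, founder_v, region_labels, mu, hotspot_weight, selection_s,
                 csr_matrix, rng, root_isotype="M"):
        if len(founder_v) < MIN_FOUNDER_V:
            raise InputError(
                f"founder V of {len(founder_v)} nt is shorter than the minimal "
                f"V region ({MIN_FOUNDER_V} nt)"
            )
        self.founder_v = founder_v
        self.region_labels = region_labels
        self.mu = mu
        self.selection_s = selection_s
        self.csr = np.asarray(csr_matrix, dtype=float)
        self.rng = rng
        rgyw, wrcy = motif_positions(founder_v)
        w = np.ones(len(founder_v))
        for p in rgyw | wrcy:
            w[p] = hotspot_weight
        self.pos_probs = w / w.sum()
        self.nodes: dict[int, LineageNode] = {
            0: LineageNode(0, None, 0, root_isotype, (), founder_v)
        }
        self.children: dict[int, list[int]] = {0: []}
        self._accept_cdr_r = min(1.0, math.exp(selection_s))
        self._accept_other = min(1.0, math.exp(-selection_s))

    def _mutate_edge(self, parent_seq: str):
        """Draw candidate mutations for one division; returns (muts, new_seq)."""
        k = self.rng.poisson(self.mu)
        if k == 0:
            return (), parent_seq
        seq = list(parent_seq)
        muts = []
        for _ in range(k):
            pos = int(self.rng.choice(len(seq), p=self.pos_probs))
            frm = seq[pos]
            to = _ALT[frm][self.rng.integers(3)]
            ci = pos // 3
            old_codon = "".join(seq[3 * ci : 3 * ci + 3])
            new_codon = old_codon[: pos % 3] + to + old_codon[pos % 3 + 1 :]
            is_repl = CODON_AA[old_codon] != CODON_AA[new_codon]
            in_cdr = self.region_labels[pos].startswith("CDR")
            p_accept = self._accept_cdr_r if (in_cdr and is_repl) else self._accept_other
            if self.rng.random() < p_accept:
                seq[pos] = to
                muts.append((pos, frm, to))
        return tuple(muts), "".join(seq)

    def _new_child(self, parent_id: int) -> int:
        parent = self.nodes[parent_id]
        muts, seq = self._mutate_edge(parent.v_seq)
        iso_idx = ISOTYPES.index(parent.isotype)
        child_iso = ISOTYPES[int(self.rng.choice(len(ISOTYPES), p=self.csr[iso_idx]))]
        nid = len(self.nodes)
        self.nodes[nid] = LineageNode(nid, parent_id, parent.depth + 1, child_iso, muts, seq)
        self.children[nid] = []
        self.children[parent_id].append(nid)
        return nid

    def sample_cell(self, depth: int) -> int:
        """Walk/grow the tree to a node at the given division depth.

        At each step an existing child is reused with probability 1/2 (which
        creates shared trunk mutations between sampled cells) and a new child
        is branched otherwise.
        """
        current = 0
        for _ in range(depth):
            kids = self.children[current]
            if kids and self.rng.random() < 0.5:
                current = kids[int(self.rng.integers(len(kids)))]
            else:
                current = self._new_child(current)
        return current


def grow_clone_lineage(founder_v, region_labels, depths, mu, hotspot_weight,
                       selection_s, csr_matrix, rng) -> tuple[Lineage, list[int]]:
    """Grow one clone lineage and sample a cell at each requested depth."""
    lin = Lineage(founder_v, region_labels, mu, hotspot_weight, selection_s, csr_matrix, rng)
    return lin, [lin.sample_cell(int(d)) for d in depths]


def _draw_dup_counts(law, n, rng) -> np.ndarray:
    kind, mean = law
    if kind == "fixed":
        return np.full(n, int(round(mean)), dtype=int)
    return rng.geometric(1.0 / mean, size=n)


def apply_sequencing_noise(molecules, pcr_dup_law, seq_error_rate, rng,
                           sample_id="sim", compartment="SLO"):
    """PCR-duplicate molecules and apply per-base substitution error.

    Returns (reads, read_truths): each molecule is emitted k >= 1 times with k
    from ``pcr_dup_law``; every emitted base is substituted independently with
    probability ``seq_error_rate``. Ground truth records error positions
    separately from true SHM.
    """
    if not 0 <= seq_error_rate <= 0.05:
        raise ConfigError("seq_error_rate: must be in [0, 0.05]")
    kind, mean = pcr_dup_law
    if kind not in ("fixed", "geometric") or mean < 1:
        raise ConfigError("pcr_dup_law: law must be fixed/geometric with mean >= 1")
    reads, truths = [], []
    dup_counts = _draw_dup_counts(pcr_dup_law, len(molecules), rng)
    for mol, k in zip(molecules, dup_counts):
        iso_class = mol.isotype[0]
        for copy in range(int(k)):
            seq = mol.sequence
            err_positions = ()
            if seq_error_rate > 0:
                n_err = rng.binomial(len(seq), seq_error_rate)
                if n_err:
                    positions = sorted(
                        int(p) for p in rng.choice(len(seq), size=n_err, replace=False)
                    )
                    s = list(seq)
                    for p in positions:
                        s[p] = _ALT[s[p]][rng.integers(3)]
                    seq = "".join(s)
                    err_positions = tuple(positions)
            rid = f"{sample_id}_{mol.population}_{iso_class}_M{mol.molecule_id:06d}_{copy}"
            reads.append(SimRead(rid, seq, sample_id, mol.population, compartment,
                                 iso_class, mol.molecule_id))
            truths.append(ReadTruth(rid, mol.molecule_id, mol.clone_id, mol.node_id,
                                    mol.population, mol.isotype, mol.true_mutations,
                                    err_positions))
    return reads, truths


def _clone_weights(n, law, alpha, rng):
    if law == "uniform":
        return np.full(n, 1.0 / n)
    # Heavy-tailed per-clone weights (Pareto tail exponent alpha): a few
    # expanded clones over a diverse background, without one clone
    # deterministically absorbing most of the repertoire.
    w = 1.0 + rng.pareto(alpha - 1.0, size=n)
    return w / w.sum()


def simulate_repertoire(config: SimConfig, reference: GermlineReference | None = None,
                        sample_id: str = "sim") -> tuple[list[SimRead], GroundTruth]:
    """Generate a sorted-population repertoire and its complete ground truth.

    Identical config + seed yields byte-identical output. Total emitted
    molecules match the population plan counts before PCR duplication.
    """
    config.validate()
    ref = reference if reference is not None else builtin_reference()
    if not ref.v_genes or not ref.j_genes:
        raise ReferenceError("empty germline reference")
    rng = np.random.default_rng(config.seed)
    v_names = sorted(ref.v_genes)
    j_names = sorted(ref.j_genes)
    gc_pops = sorted(p for p, pl in config.population_plan.items()
                     if pl.mean_divisions > 0 and pl.n_molecules > 0)
    naive_pops = sorted(p for p, pl in config.population_plan.items()
                        if pl.mean_divisions == 0 and pl.n_molecules > 0)

    def make_founder(clone_id):
        v = ref.v_genes[v_names[int(rng.integers(len(v_names)))]]
        j = ref.j_genes[j_names[int(rng.integers(len(j_names)))]]
        jl = int(3 * rng.integers(10, 21))  # junction length 30..60, in frame
        insert = "".join(_BASES[i] for i in rng.integers(4, size=jl - 6))
        junction = v.seq[-3:] + insert + j.seq[:3]
        return v, j, insert, junction

    clones: dict[int, CloneTruth] = {}
    molecules: list[Molecule] = []
    lineages: dict[int, Lineage] = {}
    clone_meta = []
    for cid in range(config.n_clones):
        v, j, insert, junction = make_founder(cid)
        spans = rng.random() < config.clone_span_prob
        if spans or not gc_pops:
            span_pool = (tuple(p for p in gc_pops if p in config.span_populations)
                         if config.span_populations is not None else tuple(gc_pops))
            allowed = span_pool if len(span_pool) >= 2 else tuple(gc_pops)
        else:
            weights = np.array([config.population_plan[p].n_molecules for p in gc_pops], float)
            weights /= weights.sum()
            allowed = (gc_pops[int(rng.choice(len(gc_pops), p=weights))],)
        clone_meta.append((cid, v, j, insert, junction, allowed))
    weights = _clone_weights(config.n_clones, config.clone_size_law, config.alpha, rng)

    # Allocate molecules per GC population over eligible clones.
    alloc: dict[int, dict[str, int]] = {cid: {} for cid in range(config.n_clones)}
    for pop in gc_pops:
        elig = [i for i, (_, _, _, _, _, allowed) in enumerate(clone_meta) if pop in allowed]
        if not elig:
            elig = list(range(config.n_clones))
        w = weights[elig] / weights[elig].sum()
        counts = rng.multinomial(config.population_plan[pop].n_molecules, w)
        for i, c in zip(elig, counts):
            if c:
                alloc[i][pop] = int(c)

    mol_id = 0
    for cid, v, j, insert, junction, _allowed in clone_meta:
        if not alloc[cid]:
            continue
        mu_edge = (config.mu_per_site * len(v.seq)) if config.mu_per_site is not None else config.mu
        lin = Lineage(v.seq, v.region_map, mu_edge, config.hotspot_weight,
                      config.selection_s, config.csr_matrix, rng)
        lineages[cid] = lin
        for pop in sorted(alloc[cid]):
            mean_d = config.population_plan[pop].mean_divisions
            for _ in range(alloc[cid][pop]):
                if config.divisions_law == "fixed":
                    d = int(round(mean_d))
                else:
                    d = int(rng.poisson(mean_d))
                nid = lin.sample_cell(d)
                node = lin.nodes[nid]
                true_muts = tuple(
                    (i, a, b) for i, (a, b) in enumerate(zip(v.seq, node.v_seq)) if a != b
                )
                n_events = sum(
                    len(lin.nodes[x].branch_mutations) for x in _path(lin.nodes, nid)
                )
                full = node.v_seq + insert + j.seq + ref.c_segments[node.isotype].seq
                molecules.append(Molecule(mol_id, cid, nid, pop, node.isotype, full,
                                          len(v.seq), true_muts, n_events))
                mol_id += 1
        clones[cid] = CloneTruth(cid, v.name, j.name, junction, insert, v.seq,
                                 dict(lin.nodes))

    # Naive-like populations: independent unmutated singleton founders.
    next_cid = config.n_clones
    for pop in naive_pops:
        for _ in range(config.population_plan[pop].n_molecules):
            v, j, insert, junction = make_founder(next_cid)
            root = LineageNode(0, None, 0, "M", (), v.seq)
            clones[next_cid] = CloneTruth(next_cid, v.name, j.name, junction, insert,
                                          v.seq, {0: root})
            full = v.seq + insert + j.seq + ref.c_segments["M"].seq
            molecules.append(Molecule(mol_id, next_cid, 0, pop, "M", full, len(v.seq), ()))
            mol_id += 1
            next_cid += 1

    reads, read_truths = apply_sequencing_noise(
        molecules, config.pcr_dup_law, config.seq_error_rate, rng, sample_id=sample_id
    )
    truth = GroundTruth(
        reads={t.read_id: t for t in read_truths},
        clones=clones,
        molecules={m.molecule_id: m for m in molecules},
    )
    return reads, truth


def reads_to_fasta(reads, path) -> None:
    with open(path, "w") as fh:
        for r in reads:
            fh.write(f">{r.read_id}\n{r.sequence}\n")


def metadata_table(reads):
    import pandas as pd

    return pd.DataFrame(
        {
            "read_id": [r.read_id for r in reads],
            "sample_id": [r.sample_id for r in reads],
            "population": [r.population for r in reads],
            "compartment": [r.compartment for r in reads],
            "isotype_primer": [r.isotype_primer for r in reads],
        }
    )
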