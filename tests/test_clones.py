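"""Clone grouping vs brute-force single linkage, collapse rules, filters."""
import math
from collections import defaultdict

import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from gcrep.clones import (apply_population_threshold, collapse_one_per_clone,
                          group_clones, stratum_counts, unique_sequence_filter)
from gcrep.annotate import annotate_reads
from gcrep.simulate import PopulationPlan, simulate_repertoire

from conftest import make_rearrangement, small_sim_config


def test_identical_junctions_form_one_clone():
    rs = [make_rearrangement(f"r{i}", junction="TGT" + "ACG" * 8 + "TGG") for i in range(2)]
    clones = group_clones(rs)
    assert len(clones) == 1 and len(clones[0].members) == 2


def test_junction_length_partitions_clones():
    a = make_rearrangement("r1", junction="A" * 30)
    b = make_rearrangement("r2", junction="A" * 33)
    assert len(group_clones([a, b])) == 2


def test_missing_junction_skipped():
    a = make_rearrangement("r1", junction="")
    b = make_rearrangement("r2", junction="A" * 30)
    clones = group_clones([a, b])
    assert sum(len(c.members) for c in clones) == 1


def _scipy_single_linkage(records, threshold):
    """Independent oracle: scipy hierarchical single linkage per partition."""
    parts = defaultdict(list)
    for r in records:
        if r.junction:
            parts[(r.v_gene, r.j_gene, len(r.junction))].append(r)
    groups = []
    for key, part in parts.items():
        if len(part) == 1:
            groups.append(frozenset([part[0].read_id]))
            continue
        n = len(part)
        d = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                mism = sum(a != b for a, b in zip(part[i].junction, part[j].junction))
                d[i, j] = d[j, i] = mism / len(part[i].junction)
        labels = fcluster(linkage(squareform(d), method="single"),
                          t=1 - threshold, criterion="distance")
        by_label = defaultdict(set)
        for r, lab in zip(part, labels):
            by_label[lab].add(r.read_id)
        groups.extend(frozenset(g) for g in by_label.values())
    return frozenset(groups)


def _random_instance(rng, n):
    """Planted clusters at ~90%/70% junction identity, random V/J context."""
    records = []
    jl = int(rng.choice([18, 21, 24, 30]))
    centers = ["".join(rng.choice(list("ACGT"), jl)) for _ in range(3)]
    for i in range(n):
        c = centers[int(rng.integers(3))]
        k = int(rng.choice([0, 1, 2, max(1, int(0.3 * jl))]))  # ~90% and ~70% variants
        junc = list(c)
        for pos in rng.choice(jl, size=k, replace=False):
            junc[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[junc[pos]]
        records.append(
            make_rearrangement(
                f"r{i:03d}", junction="".join(junc),
                v_call=str(rng.choice(["IGHV1-1*01", "IGHV2-1*01"])),
                j_call="IGHJ1*01",
            )
        )
    return records


def test_group_clones_matches_brute_force_oracle_on_random_instances():
    rng = np.random.default_rng(2024)
    for _ in range(100):
        n = int(rng.integers(2, 31))
        records = _random_instance(rng, n)
        ours = frozenset(frozenset(m.read_id for m in c.members)
                         for c in group_clones(records, 0.85))
        assert ours == _scipy_single_linkage(records, 0.85)


def test_partition_property_and_stable_ids():
    rng = np.random.default_rng(7)
    records = _random_instance(rng, 25)
    clones = group_clones(records)
    ids = [m.read_id for c in clones for m in c.members]
    assert sorted(ids) == sorted(r.read_id for r in records)  # exactly one clone each
    assert [c.clone_id for c in clones] == [f"clone_{i + 1:05d}" for i in range(len(clones))]


def test_raising_threshold_never_decreases_clone_count():
    rng = np.random.default_rng(8)
    records = _random_instance(rng, 30)
    counts = [len(group_clones(records, t)) for t in (0.70, 0.80, 0.90, 1.0)]
    assert counts == sorted(counts)


# --- clone collapse --------------------------------------------------------

def test_collapse_is_noop_for_singleton_clones():
    records = [make_rearrangement(f"r{i}", junction="A" * (30 + 3 * i)) for i in range(4)]
    clones = group_clones(records)
    assert sorted(r.read_id for r in collapse_one_per_clone(clones)) == \
        sorted(r.read_id for r in records)


def test_collapse_identical_members_keeps_exactly_one():
    records = [make_rearrangement(f"r{i}", sequence="ACGTACGT", junction="A" * 30)
               for i in range(3)]
    out = collapse_one_per_clone(group_clones(records))
    assert len(out) == 1


def test_collapse_picks_consensus_member():
    seqs = {"r1": "AAAA", "r2": "AAAT", "r3": "AATT"}
    records = [make_rearrangement(k, sequence=v, junction="A" * 30)
               for k, v in seqs.items()]
    out = collapse_one_per_clone(group_clones(records))
    assert len(out) == 1 and out[0].sequence == "AAAT"  # majority consensus is AAAT


def test_collapse_is_per_stratum_and_idempotent():
    records = [
        make_rearrangement("r1", sequence="AAAA", junction="A" * 30, population="CB"),
        make_rearrangement("r2", sequence="AAAT", junction="A" * 30, population="CB"),
        make_rearrangement("r3", sequence="AATT", junction="A" * 30, population="CC"),
    ]
    out = collapse_one_per_clone(group_clones(records))
    assert sorted(r.population for r in out) == ["CB", "CC"]
    again = collapse_one_per_clone(group_clones(out))
    assert sorted(r.read_id for r in again) == sorted(r.read_id for r in out)


# --- unique-sequence filter ------------------------------------------------

def test_unique_filter_merges_identical_sequences():
    records = [make_rearrangement(f"r{i}", sequence="ACGT" * 20, junction="A" * 30)
               for i in range(10)]
    out = unique_sequence_filter(records)
    assert len(out) == 1 and out[0].duplicate_count == 10


def test_unique_filter_drops_isolated_singletons():
    kept = [make_rearrangement(f"k{i}", sequence="ACGT" * 20, junction="A" * 30)
            for i in range(3)]
    lone = make_rearrangement("lone", sequence="TTTT" * 20, junction="C" * 33)
    out = unique_sequence_filter(kept + [lone])
    assert [r.read_id for r in out] == ["k0"]


def test_unique_filter_keeps_clone_linked_singletons():
    sup = [make_rearrangement(f"s{i}", sequence="ACGT" * 20, junction="A" * 30)
           for i in range(2)]
    # same clone (identical junction), but a genuinely distinct sequence
    variant = make_rearrangement("v1", sequence="ACGT" * 10 + "TGCA" * 10,
                                 junction="A" * 30)
    out = unique_sequence_filter(sup + [variant])
    assert sorted(r.read_id for r in out) == ["s0", "v1"]


def test_unique_filter_absorbs_near_duplicate_singletons():
    sup = [make_rearrangement(f"s{i}", sequence="ACGT" * 20, junction="A" * 30)
           for i in range(2)]
    err = make_rearrangement("e1", sequence="CCGT" + "ACGT" * 19, junction="A" * 30)
    out = unique_sequence_filter(sup + [err])
    assert [r.read_id for r in out] == ["s0"]


def test_unique_filter_idempotent():
    rng = np.random.default_rng(3)
    records = _random_instance(rng, 20)
    once = unique_sequence_filter(records)
    twice = unique_sequence_filter(once)
    assert [(r.read_id, r.duplicate_count) for r in twice] == \
        [(r.read_id, r.duplicate_count) for r in once]


def test_unique_filter_error_suppression_on_simulated_data(ref):
    """Error-derived unique sequences are mostly removed, true ones kept.

    Operating point: 2e-4/base substitution error with geometric duplication
    (mean 3), where one-error reads dominate the error class; bounds follow
    the feasibility analysis in the methods note.
    """
    config = small_sim_config(
        n_clones=30, seq_error_rate=2e-4, pcr_dup_law=("geometric", 3.0),
        population_plan={"CC": PopulationPlan(400, 6.0)}, mu=1.0, seed=4,
    )
    reads, truth = simulate_repertoire(config, ref)
    ann, _ = annotate_reads(reads, ref)
    out = unique_sequence_filter(ann)
    surviving = {r.sequence for r in out}
    mol_seqs = {m.sequence for m in truth.molecules.values()}
    error_seqs = {r.sequence for r in reads if r.sequence not in mol_seqs}
    true_retained = sum(s in surviving for s in mol_seqs) / len(mol_seqs)
    if error_seqs:
        error_removed = 1 - sum(s in surviving for s in error_seqs) / len(error_seqs)
        assert error_removed >= 0.60
    assert true_retained >= 0.88


# --- population threshold --------------------------------------------------

def test_population_threshold_boundary_behaviour():
    counts_in = {("CB", "M"): 100, ("CC", "M"): 100, ("PB", "A"): 10}
    counts_out = {("CB", "M"): 44, ("CC", "M"): 45, ("PB", "A"): 0}
    report = apply_population_threshold(counts_in, counts_out, "CLONE_COLLAPSE", 45)
    assert report.rows[("CB", "M")].excluded
    assert not report.rows[("CC", "M")].excluded
    assert report.rows[("PB", "A")].excluded
    assert report.rows[("PB", "A")].exclusion_reason == "empty"
    assert report.included_strata() == [("CC", "M")]
    for st in report.rows.values():
        assert st.reads_out <= st.reads_in


def test_stratum_counts():
    records = [make_rearrangement("r1", population="CB"),
               make_rearrangement("r2", population="CB"),
               make_rearrangement("r3", population="CC", isotype="G", subclass="G1")]
    assert stratum_counts(records) == {("CB", "M"): 2, ("CC", "G"): 1}
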