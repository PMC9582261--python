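"""Generative model: determinism, degenerate limits, closed-form expectations,
hotspot weighting, selection bias, class-switch ordering, noise model."""
import dataclasses
import io
import math

import numpy as np
import pytest

from gcrep.reference import ISOTYPES, motif_positions
from gcrep.simulate import (CODON_AA, ConfigError, InputError, Lineage, Molecule,
                            PopulationPlan, SimConfig, apply_sequencing_noise,
                            default_csr_matrix, reads_to_fasta, simulate_repertoire,
                            stepwise_csr_matrix)

from conftest import small_sim_config


@pytest.mark.parametrize(
    "overrides,field",
    [
        ({"n_clones": 0}, "n_clones"),
        ({"mu": -0.1}, "mu"),
        ({"hotspot_weight": 0.5}, "hotspot_weight"),
        ({"seq_error_rate": 0.2}, "seq_error_rate"),
        ({"alpha": 1.0}, "alpha"),
        ({"pcr_dup_law": ("fixed", 0.5)}, "pcr_dup_law"),
        ({"clone_span_prob": 1.5}, "clone_span_prob"),
        ({"divisions_law": "exact"}, "divisions_law"),
    ],
)
def test_invalid_config_names_the_field(overrides, field):
    with pytest.raises(ConfigError, match=field):
        SimConfig(**overrides).validate()


def test_csr_matrix_row_sums_and_irreversibility():
    with pytest.raises(ConfigError, match="csr_matrix"):
        m = default_csr_matrix()
        m[3, 1] = m[3, 3]  # backward switch: violates locus irreversibility
        m[3, 3] = 0.0
        SimConfig(csr_matrix=m).validate()


def test_zero_rates_reproduce_the_founder(ref):
    config = small_sim_config(mu=0.0)
    reads, truth = simulate_repertoire(config, ref)
    for r in reads:
        t = truth.reads[r.read_id]
        clone = truth.clones[t.clone_id]
        assert t.true_mutations == () and t.error_positions == ()
        assert r.sequence.startswith(clone.founder_v)


def test_seeded_determinism_gives_identical_fasta_bytes(ref):
    config = small_sim_config(seed=5, seq_error_rate=0.003, pcr_dup_law=("geometric", 2.0))
    out = []
    for _ in range(2):
        reads, _ = simulate_repertoire(config, ref)
        buf = io.StringIO()
        for r in reads:
            buf.write(f">{r.read_id}\n{r.sequence}\n")
        out.append(buf.getvalue())
    assert out[0] == out[1]


def test_molecule_counts_match_population_plan(ref):
    plan = {"CB": PopulationPlan(30, 6.0), "naive": PopulationPlan(12, 0.0)}
    _, truth = simulate_repertoire(small_sim_config(population_plan=plan), ref)
    by_pop = {}
    for m in truth.molecules.values():
        by_pop[m.population] = by_pop.get(m.population, 0) + 1
    assert by_pop == {"CB": 30, "naive": 12}


def test_mean_mutation_events_match_mu_times_divisions(ref):
    """Closed form: E[events per cell] = mu x divisions; Monte-Carlo over 20 seeds."""
    means = []
    for seed in range(20):
        config = small_sim_config(
            mu=2.0, population_plan={"CC": PopulationPlan(200, 5.0)},
            hotspot_weight=1.0, seed=seed,
        )
        _, truth = simulate_repertoire(config, ref)
        means.append(np.mean([m.n_mutation_events for m in truth.molecules.values()]))
    grand = np.mean(means)
    se = np.std(means, ddof=1) / math.sqrt(len(means))
    assert abs(grand - 10.0) < 3 * se


def test_lineage_tree_is_consistent(ref):
    """Child sequence = parent sequence with exactly the branch mutations applied."""
    _, truth = simulate_repertoire(small_sim_config(mu=2.0, seed=3), ref)
    for clone in truth.clones.values():
        for node in clone.nodes.values():
            if node.parent is None:
                assert node.v_seq == clone.founder_v
                continue
            seq = list(clone.nodes[node.parent].v_seq)
            for pos, frm, to in node.branch_mutations:
                assert seq[pos] == frm
                seq[pos] = to
            assert "".join(seq) == node.v_seq


def test_hotspot_weighting_matches_exact_multinomial(ref):
    """Sampled mutation positions hit motifs at the exact weighted expectation."""
    v = ref.v_genes["IGHV1-1*01"]
    rng = np.random.default_rng(0)
    lin = Lineage(v.seq, v.region_map, mu=1.0, hotspot_weight=4.0, selection_s=0.0,
                  csr_matrix=default_csr_matrix(), rng=rng)
    rgyw, wrcy = motif_positions(v.seq)
    hot = rgyw | wrcy
    expected = lin.pos_probs[sorted(hot)].sum()  # exact weighted multinomial mass
    n = 10_000
    draws = rng.choice(len(v.seq), size=n, p=lin.pos_probs)
    frac = np.isin(draws, sorted(hot)).mean()
    assert abs(frac - expected) < 3 * math.sqrt(expected * (1 - expected) / n)
    # and the weighting is genuinely above the unweighted census
    assert expected > len(hot) / len(v.seq)


def test_neutral_selection_accepts_everything(ref):
    v = ref.v_genes["IGHV1-1*01"]
    lin = Lineage(v.seq, v.region_map, mu=1.0, hotspot_weight=1.0, selection_s=0.0,
                  csr_matrix=default_csr_matrix(), rng=np.random.default_rng(0))
    assert lin._accept_cdr_r == 1.0 and lin._accept_other == 1.0


def test_identity_csr_keeps_founder_isotype(ref):
    config = small_sim_config(csr_matrix=np.eye(7), mu=1.0)
    _, truth = simulate_repertoire(config, ref)
    assert {m.isotype for m in truth.molecules.values()} == {"M"}


def test_stepwise_csr_rank_never_decreases_along_lineage(ref):
    config = small_sim_config(csr_matrix=stepwise_csr_matrix(0.3), mu=0.5,
                              population_plan={"PB": PopulationPlan(60, 8.0)})
    _, truth = simulate_repertoire(config, ref)
    rank = {iso: i for i, iso in enumerate(ISOTYPES)}
    seen_switched = False
    for clone in truth.clones.values():
        for node in clone.nodes.values():
            if node.parent is not None:
                assert rank[node.isotype] >= rank[clone.nodes[node.parent].isotype]
                seen_switched |= node.isotype != "M"
    assert seen_switched


def _realized_cdr_replacement_fraction(truth):
    n_cdr_r = n_tot = 0
    for clone in truth.clones.values():
        for node in clone.nodes.values():
            if node.parent is None:
                continue
            parent = clone.nodes[node.parent].v_seq
            seq = list(parent)
            for pos, frm, to in node.branch_mutations:
                ci = pos // 3
                old = "".join(seq[3 * ci : 3 * ci + 3])
                new = old[: pos % 3] + to + old[pos % 3 + 1 :]
                region = clone_region(clone, pos)
                n_tot += 1
                if region.startswith("CDR") and CODON_AA[old] != CODON_AA[new]:
                    n_cdr_r += 1
                seq[pos] = to
    return n_cdr_r / n_tot if n_tot else math.nan


_REGION_CACHE = {}


def clone_region(clone, pos):
    key = clone.v_call
    if key not in _REGION_CACHE:
        from gcrep.reference import builtin_reference

        _REGION_CACHE[key] = builtin_reference().v_genes[key].region_map
    return str(_REGION_CACHE[key][pos])


def test_positive_selection_raises_cdr_replacement_fraction(ref):
    """Paired over 20 seeds: realized CDR-R fraction at s=+1 exceeds s=0."""
    wins = 0
    for seed in range(20):
        fracs = {}
        for s in (0.0, 1.0):
            config = small_sim_config(mu=1.5, selection_s=s, seed=seed,
                                      population_plan={"CC": PopulationPlan(60, 6.0)})
            _, truth = simulate_repertoire(config, ref)
            fracs[s] = _realized_cdr_replacement_fraction(truth)
        wins += fracs[1.0] > fracs[0.0]
    assert wins >= 19


def test_mean_shm_nondecreasing_in_mu(ref):
    """Monotonicity of true per-read mutation load over mu, 10 seeds each."""
    means = []
    for mu in (0.5, 1.0, 2.0):
        per_seed = []
        for seed in range(10):
            config = small_sim_config(mu=mu, seed=seed,
                                      population_plan={"CB": PopulationPlan(40, 5.0)})
            _, truth = simulate_repertoire(config, ref)
            per_seed.append(np.mean([len(m.true_mutations) for m in truth.molecules.values()]))
        means.append(np.mean(per_seed))
    assert means[0] < means[1] < means[2]


def test_short_founder_rejected(ref):
    with pytest.raises(InputError, match="250"):
        Lineage("ACGT" * 40, None, 1.0, 1.0, 0.0, default_csr_matrix(),
                np.random.default_rng(0))


def test_trunk_and_shared_sets_on_hand_built_lineage():
    """Trunk (MRCA vs founder) equals the all-member shared set except when a
    member back-mutates a trunk position below the MRCA."""
    from gcrep.simulate import CloneTruth, LineageNode

    founder = "AAA" * 100
    def mutate(seq, muts):
        s = list(seq)
        for pos, _, to in muts:
            s[pos] = to
        return "".join(s)

    root = LineageNode(0, None, 0, "M", (), founder)
    a = LineageNode(1, 0, 1, "M", ((5, "A", "G"),), mutate(founder, ((5, "A", "G"),)))
    b = LineageNode(2, 1, 2, "M", ((10, "A", "C"),), mutate(a.v_seq, ((10, "A", "C"),)))
    c = LineageNode(3, 1, 2, "G1", ((20, "A", "T"),), mutate(a.v_seq, ((20, "A", "T"),)))
    d = LineageNode(4, 2, 3, "M", ((5, "G", "A"),), mutate(b.v_seq, ((5, "G", "A"),)))
    clone = CloneTruth(0, "IGHV1-1*01", "IGHJ1*01", "TGT" + "A" * 27, "A" * 24,
                       founder, {n.node_id: n for n in (root, a, b, c, d)})
    assert clone.mrca([2, 3]) == 1
    assert clone.trunk_positions([2, 3]) == frozenset({5})
    shared, partial, unique = clone.shared_partial_unique([2, 3])
    assert shared == clone.trunk_positions([2, 3])  # no reversion: trunk == shared
    assert unique == frozenset({10, 20}) and partial == frozenset()
    # node 4 reverted trunk position 5: shared drops it, trunk keeps it
    shared_rev, _, _ = clone.shared_partial_unique([3, 4])
    assert clone.trunk_positions([3, 4]) == frozenset({5})
    assert 5 not in shared_rev


# --- sequencing noise ------------------------------------------------------

def _toy_molecules(n, length, rng):
    seqs = ["".join(rng.choice(list("ACGT"), size=length)) for _ in range(n)]
    return [Molecule(i, 0, 0, "CB", "M", s, length, ()) for i, s in enumerate(seqs)]


def test_noise_identity_when_rates_degenerate():
    rng = np.random.default_rng(0)
    mols = _toy_molecules(20, 120, rng)
    reads, truths = apply_sequencing_noise(mols, ("fixed", 1.0), 0.0, rng)
    assert [r.sequence for r in reads] == [m.sequence for m in mols]
    assert all(t.error_positions == () for t in truths)


def test_fixed_duplication_gives_exact_group_sizes():
    rng = np.random.default_rng(1)
    mols = _toy_molecules(15, 100, rng)
    reads, _ = apply_sequencing_noise(mols, ("fixed", 3.0), 0.0, rng)
    sizes = {}
    for r in reads:
        sizes[r.molecule_id] = sizes.get(r.molecule_id, 0) + 1
    assert set(sizes.values()) == {3}


def test_error_count_matches_binomial_expectation():
    """100 molecules x 300 nt at 1% error: total errors within 3 SD of 300."""
    rng = np.random.default_rng(2)
    mols = _toy_molecules(100, 300, rng)
    _, truths = apply_sequencing_noise(mols, ("fixed", 1.0), 0.01, rng)
    total = sum(len(t.error_positions) for t in truths)
    sd = math.sqrt(100 * 300 * 0.01 * 0.99)
    assert abs(total - 300) < 3 * sd


def test_read_conservation_under_duplication(ref):
    config = small_sim_config(pcr_dup_law=("geometric", 3.0), seq_error_rate=0.001)
    reads, truth = simulate_repertoire(config, ref)
    per_mol = {}
    for r in reads:
        per_mol[r.molecule_id] = per_mol.get(r.molecule_id, 0) + 1
    assert sum(per_mol.values()) == len(reads)
    assert set(per_mol) == set(truth.molecules)
    assert all(k >= 1 for k in per_mol.values())


def test_invalid_error_rate_rejected():
    with pytest.raises(ConfigError, match="seq_error_rate"):
        apply_sequencing_noise([], ("fixed", 1.0), 0.1, np.random.default_rng(0))


def test_fasta_writer_roundtrips_ids(tmp_path, ref):
    reads, _ = simulate_repertoire(small_sim_config(), ref)
    path = tmp_path / "reads.fasta"
    reads_to_fasta(reads, path)
    lines = path.read_text().splitlines()
    assert lines[0] == f">{reads[0].read_id}" and lines[1] == reads[0].sequence
    assert len(lines) == 2 * len(reads)
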