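"""End-to-end orchestration: simulate/load -> annotate -> clone -> analyze.

One run produces, per donor sample: filter reports for both regimes, SHM
profiles and the CB-vs-CC comparison, selection results, subclass
distributions, clonality points, the cross-population overlap, a
mutation report for the largest switched clone, and a machine-readable
manifest (seed, config hash, output hash, per-stage record counts).
Identical config + seed fixes all outputs bit-exactly.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotate import annotate_read, annotate_reads
from .clones import (CLONE_COLLAPSE, UNIQUE, EmptyStratumError, apply_population_threshold,
                     collapse_one_per_clone, group_clones, stratum_counts, stratum_of,
                     unique_sequence_filter)
from .io_airr import read_airr, write_airr
from .reference import builtin_reference, load_germline
from .selection import selection_score
from .shm import InsufficientDataError, compare_cb_cc, population_shm_summary
from .simulate import SimConfig, simulate_repertoire
from .structure import (clonality_metrics, clone_mutation_report, cross_population_overlap,
                        subclass_distribution)

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    mode: str = "simulate"  # "simulate" | "fasta" | "airr"
    fasta_path: str | None = None
    metadata_path: str | None = None
    airr_path: str | None = None
    v_fasta: str | None = None
    j_fasta: str | None = None
    c_fasta: str | None = None
    clone_threshold: float = 0.85
    min_sequences: int = 45
    primer_mask: int = 0
    collapse_selector: str = "closest-to-consensus"
    expectation_hotspot_weight: float = 1.0
    expectation_transition_bias: float = 1.0
    welch: bool = True
    out_dir: str = "gcrep_out"
    seed: int = 0
    sim: SimConfig = field(default_factory=SimConfig)

    def validate(self):
        if self.mode not in ("simulate", "fasta", "airr"):
            raise ValueError("mode: must be simulate, fasta or airr")
        if self.min_sequences < 1:
            raise ValueError("min_sequences: must be >= 1")
        if not 0.5 < self.clone_threshold <= 1.0:
            raise ValueError("clone_threshold: must be in (0.5, 1.0]")

    def config_hash(self) -> str:
        def enc(o):
            if dataclasses.is_dataclass(o) and not isinstance(o, type):
                return {k: enc(v) for k, v in dataclasses.asdict(o).items()}
            if hasattr(o, "tolist"):
                return o.tolist()
            if isinstance(o, dict):
                return {str(k): enc(v) for k, v in o.items()}
            if isinstance(o, (list, tuple)):
                return [enc(v) for v in o]
            return o
        blob = json.dumps(enc(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()


def _load_reference(config: RunConfig):
    if config.v_fasta:
        return load_germline(config.v_fasta, config.j_fasta, config.c_fasta)
    return builtin_reference()


def _load_fasta_reads(fasta_path, metadata_path):
    from Bio import SeqIO

    meta = {}
    if metadata_path:
        mdf = pd.read_csv(metadata_path, sep="\t", dtype=str, keep_default_na=False)
        meta = {row["read_id"]: row for _, row in mdf.iterrows()}

    @dataclass
    class _Raw:
        read_id: str
        sequence: str
        sample_id: str = ""
        population: str = "other"
        compartment: str = "SLO"
        isotype_primer: str | None = None

    reads = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        m = meta.get(rec.id, {})
        reads.append(_Raw(rec.id, str(rec.seq).upper(), m.get("sample_id", ""),
                          m.get("population", "other"), m.get("compartment", "SLO"),
                          m.get("isotype_primer") or None))
    return reads


def _reannotate_airr(records, ref):
    """Re-derive alignments/mutations for AIRR input records from sequence."""
    out = []
    for r in records:
        ann = annotate_read(r.read_id, r.sequence, ref, sample_id=r.sample_id,
                            population=r.population, compartment=r.compartment,
                            isotype_primer=r.isotype)
        if ann is None:
            continue
        out.append(dataclasses.replace(ann, duplicate_count=r.duplicate_count,
                                       extras=r.extras))
    return out


def run_pipeline(config: RunConfig) -> dict:
    """Run the full analysis; returns result tables and writes them to out_dir."""
    config.validate()
    ref = _load_reference(config)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stages = {}

    truth = None
    if config.mode == "simulate":
        sim_config = dataclasses.replace(config.sim, seed=config.seed)
        reads, truth = simulate_repertoire(sim_config, ref)
        annotated, log = annotate_reads(reads, ref)
    elif config.mode == "fasta":
        reads = _load_fasta_reads(config.fasta_path, config.metadata_path)
        annotated, log = annotate_reads(reads, ref)
    else:
        records = read_airr(config.airr_path)
        stages["reads_in"] = len(records)
        annotated = _reannotate_airr(records, ref)
        log = None
    if log is not None:
        stages.update(reads_in=log.n_input, assigned=log.n_assigned,
                      unassignable=log.n_unassignable, frame_errors=log.n_frame_error)
    stages["annotated"] = len(annotated)
    if not annotated:
        raise RuntimeError("annotation stage produced no records")

    results: dict = {"stages": stages}

    # --- CLONE_COLLAPSE regime: SHM, selection, subclass -------------------
    clones_all = group_clones(annotated, config.clone_threshold)
    collapsed = collapse_one_per_clone(clones_all, config.collapse_selector)
    report_cc = apply_population_threshold(
        stratum_counts(annotated), stratum_counts(collapsed), CLONE_COLLAPSE,
        config.min_sequences)
    included = [r for r in collapsed if not report_cc.is_excluded(stratum_of(r))]
    stages["clones"] = len(clones_all)
    stages["collapsed"] = len(collapsed)

    profiles = population_shm_summary(included, report_cc, config.primer_mask)
    prof_rows, per_seq_rows = [], []
    for p in profiles:
        row = {"population": p.stratum[0], "isotype": p.stratum[1],
               "n_sequences": p.n_sequences, "shm_percent_median": p.shm_percent_median}
        if p.pattern is not None:
            row.update(dataclasses.asdict(p.pattern))
        prof_rows.append(row)
        per_seq_rows.extend(
            {"population": p.stratum[0], "isotype": p.stratum[1], "shm_percent": v}
            for v in p.shm_percent_values
        )
    results["shm_profiles"] = pd.DataFrame(prof_rows)
    results["shm_per_sequence"] = pd.DataFrame(per_seq_rows)

    by_stratum: dict = {}
    for p in profiles:
        by_stratum[p.stratum] = p
    cmp_rows = []
    for iso in ("M", "G", "A"):
        cb, cc = by_stratum.get(("CB", iso)), by_stratum.get(("CC", iso))
        if cb is None or cc is None:
            continue
        try:
            res = compare_cb_cc(cb.shm_percent_values, cc.shm_percent_values, config.welch)
        except InsufficientDataError:
            continue
        cmp_rows.append({"isotype": iso, "t_statistic": res.t_statistic,
                         "p_value": res.p_value, "direction": res.direction,
                         "n_CB": cb.n_sequences, "n_CC": cc.n_sequences})
    results["cb_cc_comparison"] = pd.DataFrame(cmp_rows)

    sel_rows = []
    for st in report_cc.included_strata():
        records = [r for r in included if stratum_of(r) == st]
        if not records:
            continue
        for res in selection_score(records, ref,
                                   hotspot_weight=config.expectation_hotspot_weight,
                                   transition_bias=config.expectation_transition_bias,
                                   primer_mask=config.primer_mask, stratum=st):
            sel_rows.append({"population": st[0], "isotype": st[1], "test": res.test,
                             "region": res.region, "obs_R": res.obs_R, "obs_S": res.obs_S,
                             "exp_R_frac": res.exp_R_frac, "sigma": res.sigma,
                             "ci_low": res.ci_low, "ci_high": res.ci_high,
                             "p_value": res.p_value, "no_mutations": res.no_mutations})
    results["selection"] = pd.DataFrame(sel_rows)

    sub_rows = []
    for st in report_cc.included_strata():
        if st[1] not in ("G", "A"):
            continue
        records = [r for r in included if stratum_of(r) == st]
        d = subclass_distribution(records, st[1], st)
        row = {"population": st[0], "isotype": st[1], "regime": CLONE_COLLAPSE,
               "none_fraction": d.none_fraction, "distal_index": d.distal_index,
               "empty": d.empty}
        row.update({f"frac_{s}": d.fractions[s] for s in d.fractions})
        sub_rows.append(row)
    results["subclass"] = pd.DataFrame(sub_rows)

    # --- UNIQUE regime: clonality, overlap, clone reports ------------------
    unique = unique_sequence_filter(annotated, config.clone_threshold)
    report_u = apply_population_threshold(
        stratum_counts(annotated), stratum_counts(unique), UNIQUE, config.min_sequences)
    clones_u = group_clones(unique, config.clone_threshold)
    stages["unique"] = len(unique)
    stages["clones_unique_regime"] = len(clones_u)

    clon_rows = []
    for st in report_u.included_strata():
        try:
            cp = clonality_metrics(clones_u, st)
        except EmptyStratumError:
            continue
        clon_rows.append({"population": st[0], "isotype": st[1], "regime": UNIQUE,
                          "n_clones": cp.n_clones, "n_unique_sequences": cp.n_unique_sequences,
                          "largest_clone_fraction": cp.largest_clone_fraction,
                          "expanded_fraction": cp.expanded_fraction, "gini": cp.gini,
                          "shannon_evenness": cp.shannon_evenness})
    results["clonality"] = pd.DataFrame(clon_rows)

    overlap = cross_population_overlap(clones_u)
    results["overlap"] = pd.DataFrame(
        [{"population": p, "regime": UNIQUE,
          "n_clones_in_population": overlap.n_clones_in_population[p],
          "n_shared": overlap.n_shared.get(p, 0), "pct_shared": overlap.pct_shared[p]}
         for p in overlap.populations]
    )
    results["overlap_pairs"] = pd.DataFrame(
        [{"population_a": a, "population_b": b, "n_clones": n}
         for (a, b), n in sorted(overlap.pairwise.items())]
    )
    results["overlap_membership"] = pd.DataFrame(
        [{"populations": "+".join(sorted(k)), "n_clones": v}
         for k, v in sorted(overlap.membership.items(), key=lambda kv: sorted(kv[0]))]
    )
    results["overlap_result"] = overlap

    g_clones = [c for c in clones_u
                if sum(m.isotype == "G" for m in c.members) >= 2]
    clone_report = None
    if g_clones:
        largest = max(g_clones, key=lambda c: (len(c.members), c.clone_id))
        clone_report = clone_mutation_report(largest, ref)
        results["largest_g_clone_report"] = clone_report

    # --- outputs -----------------------------------------------------------
    clone_ids = {m.read_id: c.clone_id for c in clones_all for m in c.members}
    write_airr(annotated, out / "annotated.tsv", clone_ids=clone_ids)
    frames = {
        "filter_report": pd.concat([report_cc.to_frame(), report_u.to_frame()],
                                   ignore_index=True),
        "shm_profiles": results["shm_profiles"],
        "shm_per_sequence": results["shm_per_sequence"],
        "cb_cc_comparison": results["cb_cc_comparison"],
        "selection": results["selection"],
        "subclass": results["subclass"],
        "clonality": results["clonality"],
        "overlap": results["overlap"],
        "overlap_pairs": results["overlap_pairs"],
        "overlap_membership": results["overlap_membership"],
    }
    results["filter_report_clone_collapse"] = report_cc
    results["filter_report_unique"] = report_u
    for name, df in frames.items():
        df.to_csv(out / f"{name}.tsv", sep="\t", index=False, lineterminator="\n")
    if clone_report is not None:
        (out / "largest_g_clone_report.txt").write_text(clone_report.render_text())
    if truth is not None:
        results["truth"] = truth

    digest = hashlib.sha256()
    for name in sorted(frames):
        digest.update((out / f"{name}.tsv").read_bytes())
    manifest = {
        "gcrep_version": __version__, "seed": config.seed,
        "config_hash": config.config_hash(), "outputs_sha256": digest.hexdigest(),
        "stages": stages,
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    results["manifest"] = manifest
    for stage, count in stages.items():
        logger.info("stage %s: %s records", stage, count)
    return results
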