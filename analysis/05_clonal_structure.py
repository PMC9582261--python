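"""Clonality, cross-population clonal overlap, and the largest-clone report.

The unique-sequence regime feeds these. Writes per-donor TSVs and the
largest switched-clone alignment under results/clonal_structure/, and
prints the per-population shared-clone percentages — the signature that
separates confined (CB/CC-only) from broad (recycling-like) overlap.
"""
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from common import RESULTS, donor_configs, load_annotated
from gcrep.clones import (UNIQUE, apply_population_threshold, group_clones,
                          stratum_counts, unique_sequence_filter)
from gcrep.clones import EmptyStratumError
from gcrep.structure import (clonality_metrics, clone_mutation_report,
                             cross_population_overlap)


def main():
    out_dir = RESULTS / "clonal_structure"
    out_dir.mkdir(parents=True, exist_ok=True)
    for donor in donor_configs():
        ann, ref = load_annotated(donor)
        unique = unique_sequence_filter(ann)
        report = apply_population_threshold(
            stratum_counts(ann), stratum_counts(unique), UNIQUE)
        clones = group_clones(unique)

        clon_rows = []
        for st in report.included_strata():
            try:
                cp = clonality_metrics(clones, st)
            except EmptyStratumError:
                continue
            clon_rows.append({"donor": donor, "population": st[0], "isotype": st[1],
                              "n_clones": cp.n_clones,
                              "n_unique_sequences": cp.n_unique_sequences,
                              "largest_clone_fraction": cp.largest_clone_fraction,
                              "expanded_fraction": cp.expanded_fraction,
                              "gini": cp.gini, "shannon_evenness": cp.shannon_evenness})
        pd.DataFrame(clon_rows).to_csv(out_dir / f"{donor}_clonality.tsv", sep="\t",
                                       index=False, lineterminator="\n")

        overlap = cross_population_overlap(clones, donor=donor)
        pd.DataFrame(
            [{"donor": donor, "population": p,
              "n_clones": overlap.n_clones_in_population[p],
              "n_shared": overlap.n_shared.get(p, 0),
              "pct_shared": overlap.pct_shared[p]}
             for p in overlap.populations]
        ).to_csv(out_dir / f"{donor}_overlap.tsv", sep="\t", index=False,
                 lineterminator="\n")

        g_clones = [c for c in clones if sum(m.isotype == "G" for m in c.members) >= 2]
        if g_clones:
            largest = max(g_clones, key=lambda c: (len(c.members), c.clone_id))
            rep = clone_mutation_report(largest, ref)
            (out_dir / f"{donor}_largest_g_clone.txt").write_text(rep.render_text())

        print(f"\n{donor}: shared-clone percentage per population (UNIQUE regime)")
        for p in overlap.populations:
            print(f"  {p:>6}: {overlap.pct_shared[p]:5.1f}% "
                  f"({overlap.n_shared.get(p, 0)}/{overlap.n_clones_in_population[p]} clones)")


if __name__ == "__main__":
    main()
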