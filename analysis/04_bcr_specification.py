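"""SHM levels/patterns, CB-vs-CC comparison, selection, subclass usage.

The clone-collapse regime feeds all of these summaries. Writes per-donor
TSVs under results/bcr_specification/ and prints the cross-donor story:
median SHM by population, whether CC shows lower SHM than CB (the
selection footprint), the CDR selection score, and the distal IGHG index.
"""
import dataclasses
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))

import pandas as pd

from common import RESULTS, donor_configs, load_annotated
from gcrep.clones import (CLONE_COLLAPSE, apply_population_threshold,
                          collapse_one_per_clone, group_clones, stratum_counts,
                          stratum_of)
from gcrep.shm import InsufficientDataError, compare_cb_cc, population_shm_summary
from gcrep.selection import selection_score
from gcrep.structure import subclass_distribution


def main():
    out_dir = RESULTS / "bcr_specification"
    out_dir.mkdir(parents=True, exist_ok=True)
    for donor in donor_configs():
        ann, ref = load_annotated(donor)
        collapsed = collapse_one_per_clone(group_clones(ann))
        report = apply_population_threshold(
            stratum_counts(ann), stratum_counts(collapsed), CLONE_COLLAPSE)
        included = [r for r in collapsed if not report.is_excluded(stratum_of(r))]

        profiles = population_shm_summary(included, report)
        prof_rows = []
        for p in profiles:
            row = {"donor": donor, "population": p.stratum[0], "isotype": p.stratum[1],
                   "n": p.n_sequences, "shm_percent_median": p.shm_percent_median}
            if p.pattern is not None:
                row.update(dataclasses.asdict(p.pattern))
            prof_rows.append(row)
        pd.DataFrame(prof_rows).to_csv(out_dir / f"{donor}_shm_profiles.tsv",
                                       sep="\t", index=False, lineterminator="\n")

        by = {p.stratum: p for p in profiles}
        cmp_rows, sel_rows, sub_rows = [], [], []
        for iso in ("M", "G"):
            cb, cc = by.get(("CB", iso)), by.get(("CC", iso))
            if cb and cc:
                try:
                    t = compare_cb_cc(cb.shm_percent_values, cc.shm_percent_values)
                except InsufficientDataError:
                    continue
                cmp_rows.append({"donor": donor, "isotype": iso,
                                 "median_CB": cb.shm_percent_median,
                                 "median_CC": cc.shm_percent_median,
                                 "t": t.t_statistic, "p": t.p_value,
                                 "direction": t.direction})
        for st in report.included_strata():
            records = [r for r in included if stratum_of(r) == st]
            for res in selection_score(records, ref, stratum=st):
                sel_rows.append({"donor": donor, "population": st[0], "isotype": st[1],
                                 "test": res.test, "region": res.region,
                                 "obs_R": res.obs_R, "obs_S": res.obs_S,
                                 "exp_R_frac": res.exp_R_frac, "sigma": res.sigma,
                                 "p_value": res.p_value})
            if st[1] == "G":
                d = subclass_distribution(records, "G", st)
                if not d.empty:
                    sub_rows.append({"donor": donor, "population": st[0],
                                     "distal_index": d.distal_index,
                                     **{f"frac_{s}": f for s, f in d.fractions.items()}})
        pd.DataFrame(cmp_rows).to_csv(out_dir / f"{donor}_cb_cc.tsv", sep="\t",
                                      index=False, lineterminator="\n")
        pd.DataFrame(sel_rows).to_csv(out_dir / f"{donor}_selection.tsv", sep="\t",
                                      index=False, lineterminator="\n")
        pd.DataFrame(sub_rows).to_csv(out_dir / f"{donor}_subclass.tsv", sep="\t",
                                      index=False, lineterminator="\n")

        print(f"\n{donor}:")
        for row in cmp_rows:
            trend = "CB > CC" if row["direction"] > 0 else "CB <= CC"
            print(f"  IGH{row['isotype']}: median SHM CB {row['median_CB']:.2f}% vs "
                  f"CC {row['median_CC']:.2f}% ({trend}, p={row['p']:.3g})")
        cc_sel = [r for r in sel_rows if r["population"] == "CC" and r["test"] == "rs"
                  and r["region"] == "CDR" and r["isotype"] == "M"]
        for r in cc_sel:
            print(f"  CC IGHM CDR selection sigma = {r['sigma']:.3f} "
                  f"(p={r['p_value']:.3g})")
        for r in sub_rows:
            if r["population"] == "CC":
                print(f"  CC IGHG distal subclass index = {r['distal_index']:.3f}")


if __name__ == "__main__":
    main()
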