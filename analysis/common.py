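"""Shared cohort definition and helpers for the numbered analysis drivers.

Three synthetic donors emulate the qualitative archetypes the analysis is
designed to separate:

* HD      — healthy-like: normal SHM, positive selection, class switching,
            clonal overlap confined to the CB/CC axis.
* P2like  — impaired SHM induction: low per-division mutation rate, no
            selection, reduced switching with proximal IGHG bias.
* P3like  — recycling-like: high SHM, no selection, expanded clones spanning
            all GC populations.
"""
from pathlib import Path

import numpy as np

from gcrep.io_airr import read_airr
from gcrep.pipeline import _reannotate_airr
from gcrep.reference import ISOTYPES, builtin_reference
from gcrep.simulate import SimConfig, default_csr_matrix

RESULTS = Path(__file__).resolve().parent.parent / "results"


def proximal_biased_csr_matrix(switch_rate=0.06):
    """Like the default matrix, but switch mass shifted to proximal classes."""
    weights = {"G3": 0.45, "G1": 0.40, "A1": 0.05, "G2": 0.06, "G4": 0.02, "A2": 0.02}
    n = len(ISOTYPES)
    m = np.zeros((n, n))
    for i, iso in enumerate(ISOTYPES):
        rate = switch_rate if iso == "M" else switch_rate / 4
        targets = ISOTYPES[i + 1:]
        if not targets:
            m[i, i] = 1.0
            continue
        w = np.array([weights[t] for t in targets])
        w = w / w.sum()
        m[i, i + 1:] = rate * w
        m[i, i] = 1.0 - rate
    return m


def donor_configs(base_seed: int = 11) -> dict[str, SimConfig]:
    return {
        "HD": SimConfig(
            selection_s=0.7, clone_span_prob=0.2, span_populations=("CB", "CC"),
            seed=base_seed,
        ),
        "P2like": SimConfig(
            mu=0.5, selection_s=0.0, csr_matrix=proximal_biased_csr_matrix(0.05),
            clone_span_prob=0.2, span_populations=("CB", "CC"), seed=base_seed + 1,
        ),
        "P3like": SimConfig(
            mu=2.5, selection_s=0.0, alpha=1.7, clone_span_prob=0.65,
            seed=base_seed + 2,
        ),
    }


def load_annotated(donor: str):
    """Annotated records for one donor (mutations re-derived from sequence)."""
    ref = builtin_reference()
    path = RESULTS / "annotated" / f"{donor}.tsv"
    if not path.exists():
        raise SystemExit(f"{path} missing - run analysis/02_annotate_reads.py first")
    return _reannotate_airr(read_airr(path), ref), ref
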