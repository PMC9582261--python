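import dataclasses

import pytest

from gcrep.annotate import Rearrangement
from gcrep.reference import builtin_reference
from gcrep.simulate import PopulationPlan, SimConfig, simulate_repertoire


@pytest.fixture(scope="session")
def ref():
    return builtin_reference()


def small_sim_config(**overrides):
    """A small, fast simulation: one GC population, clean reads by default."""
    base = dict(
        n_clones=6,
        population_plan={"CC": PopulationPlan(40, 5.0)},
        mu=1.2,
        hotspot_weight=3.0,
        selection_s=0.0,
        seq_error_rate=0.0,
        pcr_dup_law=("fixed", 1.0),
        seed=0,
    )
    base.update(overrides)
    return SimConfig(**base)


@pytest.fixture(scope="session")
def clean_sim():
    """A noise-free default-scale repertoire shared across read-only tests."""
    config = dataclasses.replace(SimConfig(seed=11), seq_error_rate=0.0,
                                 pcr_dup_law=("fixed", 1.0))
    return simulate_repertoire(config)


def make_rearrangement(read_id, sequence="ACGT", junction="TGTGCAAAATGG",
                       v_call="IGHV1-1*01", j_call="IGHJ1*01", population="CB",
                       isotype="M", subclass="M", duplicate_count=1, mutations=(),
                       v_valid_length=300, **kw):
    """Minimal Rearrangement for unit tests of clone/summary logic."""
    return Rearrangement(
        read_id=read_id, sequence=sequence, v_call=v_call, j_call=j_call,
        v_identity=1.0, junction=junction, mutations=tuple(mutations),
        isotype=isotype, subclass=subclass, population=population,
        duplicate_count=duplicate_count, v_valid_length=v_valid_length,
        v_germline_length=v_valid_length, **kw,
    )
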