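"""AIRR Rearrangement TSV input/output.

Follows the AIRR Community Rearrangement schema conventions: tab-separated,
header row, required columns ``sequence_id``, ``sequence``, ``v_call``,
``j_call``, ``junction``.  Unknown columns are preserved on read and written
back after the known ones, so ground-truth ``sim_`` columns from the
simulator round-trip through the pipeline.  Output is byte-deterministic
for fixed input.
"""
from __future__ import annotations

from pathlib import Path

import pandas as pd

from .annotate import Rearrangement

REQUIRED_COLUMNS = ("sequence_id", "sequence", "v_call", "j_call", "junction")
KNOWN_COLUMNS = REQUIRED_COLUMNS + (
    "v_identity", "productive", "sample_id", "population", "compartment",
    "isotype", "subclass", "duplicate_count", "mutation_count", "clone_id",
)


class SchemaError(ValueError):
    pass


def read_airr(path) -> list[Rearrangement]:
    """Parse an AIRR Rearrangement TSV into Rearrangement records.

    Mutations are not representable in the flat schema; records come back
    with an empty mutation list (the pipeline re-derives them from
    ``sequence`` against the called V when needed). Unknown columns are kept
    in ``extras``.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing required AIRR column '{col}'")
    extra_cols = [c for c in df.columns if c not in KNOWN_COLUMNS]
    records = []
    for row in df.itertuples(index=False):
        d = row._asdict()
        records.append(
            Rearrangement(
                read_id=d["sequence_id"], sequence=d["sequence"], v_call=d["v_call"],
                j_call=d["j_call"], junction=d["junction"],
                v_identity=float(d["v_identity"]) if d.get("v_identity") else 1.0,
                mutations=(),
                isotype=d.get("isotype") or None,
                subclass=d.get("subclass") or "none",
                sample_id=d.get("sample_id", ""),
                population=d.get("population") or "other",
                compartment=d.get("compartment") or "SLO",
                duplicate_count=int(d["duplicate_count"]) if d.get("duplicate_count") else 1,
                productive=(d.get("productive", "T") in ("T", "TRUE", "True", "true", "1")),
                extras=tuple((c, d[c]) for c in extra_cols),
            )
        )
    return records


def to_airr_frame(records) -> pd.DataFrame:
    rows = []
    extra_cols: list[str] = []
    for r in records:
        row = {
            "sequence_id": r.read_id, "sequence": r.sequence, "v_call": r.v_call,
            "j_call": r.j_call, "junction": r.junction,
            "v_identity": f"{r.v_identity:.6f}",
            "productive": "T" if r.productive else "F",
            "sample_id": r.sample_id, "population": r.population,
            "compartment": r.compartment, "isotype": r.isotype or "",
            "subclass": r.subclass, "duplicate_count": str(r.duplicate_count),
            "mutation_count": str(len(r.mutations)),
        }
        for k, v in r.extras:
            row[k] = v
            if k not in extra_cols:
                extra_cols.append(k)
        rows.append(row)
    cols = [c for c in KNOWN_COLUMNS if c != "clone_id"] + sorted(extra_cols)
    df = pd.DataFrame(rows, columns=cols)
    return df.fillna("")


def write_airr(records, path, clone_ids: dict | None = None) -> None:
    """Write records as AIRR TSV; stable column order, deterministic bytes.

    ``clone_ids`` optionally maps read_id -> clone_id and adds the clone_id
    column.
    """
    df = to_airr_frame(records)
    if clone_ids is not None:
        df["clone_id"] = [clone_ids.get(r, "") for r in df["sequence_id"]]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def sim_truth_columns(reads, truth) -> list[tuple]:
    """Ground-truth ``sim_`` extras for simulator reads (AIRR export)."""
    out = []
    for r in reads:
        t = truth.reads[r.read_id]
        out.append(
            (
                ("sim_clone_id", str(t.clone_id)),
                ("sim_population", t.population),
                ("sim_isotype", t.isotype),
                ("sim_molecule_id", str(t.molecule_id)),
                ("sim_n_true_mutations", str(len(t.true_mutations))),
                ("sim_n_errors", str(len(t.error_positions))),
            )
        )
    return out
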