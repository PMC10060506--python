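"""Cohort-table ingestion, variable-name mapping, and tabular output contracts.

Cohort CSV contract (the "native" layout): one row per patient with a
``patient_id`` column, optional ``age`` and ``diabetes_duration`` columns,
one column per network node (raw units), diagnosis columns named
``diag_<phenotype>`` (baseline) and ``followup_<phenotype>``.  Empty cells
and ``NA`` mark missing values.

Survey-style tables with foreign column names (e.g. NHANES ``lbxglu``,
``bmxbmi``, ``diq080``) are absorbed through a :class:`VariableDictionary`
that renames columns, applies positive unit-conversion factors, and recodes
categorical diagnosis answers (e.g. ``yes``/``no``) to {0, 1}.

All numeric output tables are written with 12 significant digits so reruns
can be compared byte for byte.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .network import GeneralizedStoichiometry
from .twin import DigitalTwin, PatientRecord

__all__ = [
    "VariableDictionary",
    "read_cohort",
    "write_cohort",
    "twins_to_frame",
    "write_table",
    "FLOAT_FORMAT",
]

FLOAT_FORMAT = "%.12g"
_NA_STRINGS = {"", "na", "nan", "none", "null", "."}


@dataclass(frozen=True)
class VariableDictionary:
    """Column mapping from a source table to model node ids.

    ``columns`` maps source column -> (node id, unit conversion factor);
    ``diagnoses`` maps source column -> (phenotype, recoding map, is_followup).
    """

    id_column: str = "patient_id"
    age_column: str | None = "age"
    duration_column: str | None = "diabetes_duration"
    columns: Mapping[str, tuple[str, float]] = field(default_factory=dict)
    diagnoses: Mapping[str, tuple[str, Mapping[str, int], bool]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        for src, (node, factor) in self.columns.items():
            if not factor > 0:
                raise ValueError(f"conversion factor for {src!r} must be positive")

    def validate_against(self, model: GeneralizedStoichiometry) -> None:
        known = set(model.node_ids)
        bad = [n for n, _ in self.columns.values() if n not in known]
        if bad:
            raise ValueError(f"dictionary targets unknown node id(s): {sorted(set(bad))}")

    @classmethod
    def from_file(cls, path: str | Path) -> "VariableDictionary":
        path = Path(path)
        raw = (
            json.loads(path.read_text())
            if path.suffix.lower() == ".json"
            else yaml.safe_load(path.read_text())
        )
        columns = {
            src: (spec["node"], float(spec.get("factor", 1.0)))
            if isinstance(spec, dict)
            else (str(spec), 1.0)
            for src, spec in (raw.get("columns") or {}).items()
        }
        diagnoses = {
            src: (
                spec["phenotype"],
                {str(k).lower(): int(v) for k, v in (spec.get("recode") or {}).items()},
                bool(spec.get("followup", False)),
            )
            for src, spec in (raw.get("diagnoses") or {}).items()
        }
        return cls(
            id_column=raw.get("id_column", "patient_id"),
            age_column=raw.get("age_column", "age"),
            duration_column=raw.get("duration_column", "diabetes_duration"),
            columns=columns,
            diagnoses=diagnoses,
        )


def _parse_cell(value) -> float | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, str) and value.strip().lower() in _NA_STRINGS:
        return None
    return float(value)


def _recode(value, recoding: Mapping[str, int], column: str) -> int | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    key = str(value).strip().lower()
    if key in _NA_STRINGS:
        return None
    if recoding:
        if key in recoding:
            return recoding[key]
        raise ValueError(f"column {column!r}: unmapped categorical value {value!r}")
    return int(float(value))


def read_cohort(
    csv_path: str | Path,
    dictionary: VariableDictionary | None = None,
    model: GeneralizedStoichiometry | None = None,
) -> list[PatientRecord]:
    """Read one patient per CSV row, applying the variable dictionary if given.

    Without a dictionary, columns are assumed to already use node ids, with
    ``diag_``/``followup_`` prefixes for diagnosis columns.  Duplicate
    patient ids raise; NA/empty cells become missing readings.
    """
    df = pd.read_csv(csv_path, dtype=str)
    d = dictionary or _native_dictionary(df.columns)
    if model is not None and dictionary is not None:
        d.validate_against(model)
    if d.id_column not in df.columns:
        raise ValueError(f"cohort table lacks the id column {d.id_column!r}")
    ids = df[d.id_column].astype(str)
    dupes = ids[ids.duplicated()].unique().tolist()
    if dupes:
        raise ValueError(f"duplicate patient id(s): {dupes}")

    known_nodes = set(model.node_ids) if model is not None else None
    records = []
    for _, row in df.iterrows():
        readings: dict[str, float] = {}
        for src, (node, factor) in d.columns.items():
            if src not in df.columns:
                continue
            if known_nodes is not None and node not in known_nodes:
                continue
            val = _parse_cell(row[src])
            if val is not None:
                readings[node] = val * factor
        baseline: dict[str, int] = {}
        followup: dict[str, int] = {}
        for src, (phen, recoding, is_fu) in d.diagnoses.items():
            if src not in df.columns:
                continue
            val = _recode(row[src], recoding, src)
            if val is not None:
                (followup if is_fu else baseline)[phen] = val
        records.append(
            PatientRecord(
                patient_id=str(row[d.id_column]),
                readings=readings,
                age=_parse_cell(row[d.age_column]) if d.age_column in df.columns else None,
                diabetes_duration=(
                    _parse_cell(row[d.duration_column])
                    if d.duration_column in df.columns
                    else None
                ),
                diagnoses_baseline=baseline,
                diagnoses_followup=followup,
            )
        )
    return records


def _native_dictionary(columns: Sequence[str]) -> VariableDictionary:
    reserved = {"patient_id", "age", "diabetes_duration"}
    value_cols = {}
    diagnoses = {}
    for c in columns:
        if c in reserved:
            continue
        if c.startswith("diag_"):
            diagnoses[c] = (c[len("diag_"):], {}, False)
        elif c.startswith("followup_"):
            diagnoses[c] = (c[len("followup_"):], {}, True)
        else:
            value_cols[c] = (c, 1.0)
    return VariableDictionary(columns=value_cols, diagnoses=diagnoses)


def write_cohort(records: Sequence[PatientRecord], path: str | Path) -> Path:
    """Write records in the native cohort CSV layout (inverse of read_cohort)."""
    node_ids = sorted({n for r in records for n in r.readings})
    baseline = sorted({p for r in records for p in r.diagnoses_baseline})
    followup = sorted({p for r in records for p in r.diagnoses_followup})
    rows = []
    for r in records:
        row: dict = {"patient_id": r.patient_id}
        if r.age is not None:
            row["age"] = r.age
        if r.diabetes_duration is not None:
            row["diabetes_duration"] = r.diabetes_duration
        for n in node_ids:
            row[n] = r.readings.get(n, np.nan)
        for p in baseline:
            row[f"diag_{p}"] = r.diagnoses_baseline.get(p, np.nan)
        for p in followup:
            row[f"followup_{p}"] = r.diagnoses_followup.get(p, np.nan)
        rows.append(row)
    df = pd.DataFrame(rows)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path


def twins_to_frame(
    twins: Sequence[DigitalTwin], model: GeneralizedStoichiometry
) -> pd.DataFrame:
    """Flux table: one row per patient, one ``v_<flux>`` column per flux."""
    rows = []
    for t in twins:
        row: dict = {
            "patient_id": t.patient_id,
            "solver_status": t.solver_status,
            "relaxed": t.relaxed,
            "objective_value": t.objective_value,
        }
        for j, fid in enumerate(model.flux_ids):
            row[f"v_{fid}"] = t.v[j] if t.v is not None else np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def write_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
    return path
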