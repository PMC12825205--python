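"""Readers and writers for the package's CSV/JSON dialects, plus run
manifests.

Dialects:

* parameter / initial-condition fixtures: JSON ``{"name": value}`` or flat
  CSV ``name,value,units``; the two round-trip exactly.
* observation tables: tidy CSV ``protein,dose_ng_ml,time_h,replicate,
  fold_change`` (normalized dialect) or with ``mfi,baseline_mfi,
  background_mfi`` instead of ``fold_change`` (raw dialect).
* viability tables: ``treatment,pct_viable,pct_apoptotic,pct_necrotic,
  prl_pre_exposed,shear,trail_dose_ng_ml``.
* cohort tables: Table-1-shaped CSV with ';'-separated intervention lists
  and empty cells for missing values.
"""

from __future__ import annotations

import json
import time
import uuid
from dataclasses import asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import DataError
from .metrics import CohortRecord, ExpressionMeasurement, ViabilityRecord, \
    normalized_expression

__all__ = [
    "write_params_json", "write_params_csv", "read_params",
    "write_observations_csv", "read_observations_csv",
    "write_viability_csv", "read_viability_csv",
    "write_cohort_csv", "read_cohort_csv",
    "write_manifest",
]


def write_params_json(table: Mapping[str, float], path) -> None:
    Path(path).write_text(
        json.dumps({k: float(v) for k, v in table.items()}, indent=1) + "\n")


def write_params_csv(table: Mapping[str, float], path,
                     units: Mapping[str, str] | None = None) -> None:
    lines = ["name,value,units"]
    for k, v in table.items():
        lines.append(f"{k},{v!r},{(units or {}).get(k, '')}")
    Path(path).write_text("\n".join(lines) + "\n")


def read_params(path) -> dict[str, float]:
    from .network import _load_table
    return _load_table(path)


def write_observations_csv(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, index=False)


def read_observations_csv(path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    cols = set(frame.columns)
    if "fold_change" in cols:
        return frame
    raw_needed = {"mfi", "baseline_mfi", "background_mfi"}
    if raw_needed <= cols:
        folds = []
        for _, row in frame.iterrows():
            m = ExpressionMeasurement(
                f_protein=row["mfi"], f_baseline=row["baseline_mfi"],
                f_background=row["background_mfi"])
            folds.append(normalized_expression(m))
        out = frame.drop(columns=sorted(raw_needed)).copy()
        out["fold_change"] = folds
        return out
    raise DataError(
        f"observation CSV needs either a fold_change column or the raw "
        f"columns {sorted(raw_needed)}; got {sorted(cols)}")


def write_viability_csv(records: Iterable[ViabilityRecord], path) -> None:
    pd.DataFrame([asdict(r) for r in records]).to_csv(path, index=False)


def read_viability_csv(path) -> list[ViabilityRecord]:
    frame = pd.read_csv(path)
    return [ViabilityRecord(
        treatment=row["treatment"], pct_viable=float(row["pct_viable"]),
        pct_apoptotic=float(row["pct_apoptotic"]),
        pct_necrotic=float(row["pct_necrotic"]),
        prl_pre_exposed=bool(row["prl_pre_exposed"]),
        shear=bool(row["shear"]),
        trail_dose_ng_ml=float(row["trail_dose_ng_ml"]))
        for _, row in frame.iterrows()]


def _opt_float(value):
    if value is None or (isinstance(value, float) and np.isnan(value)) \
            or value == "":
        return None
    return float(value)


def _split_list(value) -> tuple[str, ...]:
    if value is None or (isinstance(value, float) and np.isnan(value)) \
            or str(value).strip() == "":
        return ()
    return tuple(s.strip() for s in str(value).split(";") if s.strip())


def read_cohort_csv(path) -> list[CohortRecord]:
    frame = pd.read_csv(path, dtype={"trimester": str, "stage": str})
    records = []
    for _, row in frame.iterrows():
        trimester = row.get("trimester")
        if isinstance(trimester, float) and np.isnan(trimester):
            trimester = None
        records.append(CohortRecord(
            patient_id=str(row["patient_id"]),
            age=_opt_float(row.get("age")),
            pregnant=bool(row["pregnant"] in (True, "True", "true", 1)),
            trimester=trimester,
            tumor_location=str(row["tumor_location"]),
            tumor_size_cm=_opt_float(row.get("tumor_size_cm")),
            stage=str(row.get("stage", "")),
            procedures=_split_list(row.get("procedures")),
            systemic_treatments=_split_list(row.get("systemic_treatments")),
            vital_status=str(row.get("vital_status", "A"))))
    return records


def write_cohort_csv(records: Iterable[CohortRecord], path) -> None:
    rows = []
    for r in records:
        rows.append({
            "patient_id": r.patient_id,
            "age": "" if r.age is None else (
                int(r.age) if float(r.age).is_integer() else r.age),
            "pregnant": r.pregnant,
            "trimester": r.trimester or "",
            "tumor_location": r.tumor_location,
            "tumor_size_cm": "" if r.tumor_size_cm is None
            else r.tumor_size_cm,
            "stage": r.stage,
            "procedures": ";".join(r.procedures),
            "systemic_treatments": ";".join(r.systemic_treatments),
            "vital_status": r.vital_status,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def write_manifest(path, command: str, config: Mapping, seeds: Mapping,
                   outputs: Sequence[str], started: float) -> dict:
    """Append a run manifest entry (JSON lines; append-only)."""
    entry = {
        "run_id": uuid.uuid4().hex[:12],
        "command": command,
        "config": dict(config),
        "seeds": dict(seeds),
        "outputs": list(outputs),
        "started_unix": started,
        "finished_unix": time.time(),
    }
    with open(path, "a") as fh:
        fh.write(json.dumps(entry) + "\n")
    return entry
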