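"""CSV/JSON record and report I/O.

Input CSV, one row per test (comma-separated, UTF-8, '.' decimals):
``id, sex {M,F}, age, body_mass_kg (opt), po_standard_w, po_high_w,
hr_standard, hr_high, measured_vo2max_l_min (opt)``. Alternatively
``kp_standard, kp_high, rpm`` may replace the power columns and are
converted with the Monark kp→watt relation. Unknown extra columns are
preserved on pass-through outputs.
"""

from __future__ import annotations

import dataclasses
import json
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .agreement import AgreementReport, StratumResult
from .estimators import kp_rpm_to_watts
from .exceptions import FormatError
from .records import Estimate, Sex, TestRecord

REPORT_SCHEMA_VERSION = "1.0"

_REQUIRED = ("id", "sex", "age", "hr_standard", "hr_high")
_POWER_W = ("po_standard_w", "po_high_w")
_POWER_KP = ("kp_standard", "kp_high", "rpm")


@dataclasses.dataclass
class RowError:
    row: int          # 1-based data-row number (header excluded)
    id: str
    message: str


def read_records(path) -> Tuple[List[TestRecord], List[RowError]]:
    """Read and validate test records from a CSV file.

    Rows that violate record invariants are collected into the returned
    error list (with their row number) while valid rows are still parsed.
    A missing required *column* raises :class:`FormatError` immediately.
    """
    df = pd.read_csv(path)
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise FormatError(f"input file missing required column(s): {missing}")
    has_w = all(c in df.columns for c in _POWER_W)
    has_kp = all(c in df.columns for c in _POWER_KP)
    if not (has_w or has_kp):
        raise FormatError(
            f"input file needs either {list(_POWER_W)} or {list(_POWER_KP)} columns")
    records: List[TestRecord] = []
    errors: List[RowError] = []
    for i, row in df.iterrows():
        rowno = int(i) + 1
        try:
            if has_w and not (pd.isna(row["po_standard_w"]) or pd.isna(row["po_high_w"])):
                po_std, po_high = float(row["po_standard_w"]), float(row["po_high_w"])
            else:
                po_std = kp_rpm_to_watts(float(row["kp_standard"]), float(row["rpm"]))
                po_high = kp_rpm_to_watts(float(row["kp_high"]), float(row["rpm"]))
            mass = row.get("body_mass_kg")
            meas = row.get("measured_vo2max_l_min")
            records.append(TestRecord(
                sex=Sex.parse(row["sex"]), age=float(row["age"]),
                hr_standard=float(row["hr_standard"]), hr_high=float(row["hr_high"]),
                po_standard=po_std, po_high=po_high,
                body_mass=None if mass is None or pd.isna(mass) else float(mass),
                measured_vo2max=None if meas is None or pd.isna(meas) else float(meas),
                id=str(row["id"])))
        except (ValueError, KeyError, TypeError) as exc:
            errors.append(RowError(rowno, str(row.get("id", "")), str(exc)))
    return records, errors


def estimates_frame(records: Sequence[TestRecord],
                    estimates: Sequence[Estimate]) -> pd.DataFrame:
    """Tabulate estimates alongside record identifiers.

    Estimates are reported at 2 dp (L·min⁻¹) and 1 dp (mL·kg⁻¹·min⁻¹);
    warnings are serialised as a semicolon-joined string (empty allowed).
    """
    rows = []
    for rec, est in zip(records, estimates):
        r = est.rounded()
        rows.append({
            "id": rec.id, "sex": rec.sex.value, "method": r.method,
            "vo2max_l_min": r.vo2max_abs,
            "vo2max_ml_kg_min": r.vo2max_rel,
            "in_valid_range": r.in_valid_range,
            "warnings": ";".join(r.warnings),
        })
    return pd.DataFrame(rows)


def write_estimates(records: Sequence[TestRecord], estimates: Sequence[Estimate],
                    path) -> None:
    estimates_frame(records, estimates).to_csv(path, index=False, lineterminator="\n")


def read_estimates(path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False,
                     converters={"warnings": str})
    for col in ("vo2max_l_min", "vo2max_ml_kg_min"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce")
    return df


def _clean(value):
    if isinstance(value, float) and not np.isfinite(value):
        return None
    return value


def report_to_dict(report: AgreementReport) -> dict:
    return {k: _clean(v) for k, v in dataclasses.asdict(report).items()}


def write_report(strata: Sequence[StratumResult], path, meta: Optional[dict] = None) -> None:
    """Serialise a stratified agreement report to versioned JSON."""
    payload = {
        "schema_version": REPORT_SCHEMA_VERSION,
        "meta": meta or {},
        "strata": [
            {"label": s.label, "n": s.n,
             "report": None if s.report is None else report_to_dict(s.report)}
            for s in strata
        ],
    }
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2)
        fh.write("\n")


def read_report(path) -> dict:
    with open(path, encoding="utf-8") as fh:
        return json.load(fh)
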