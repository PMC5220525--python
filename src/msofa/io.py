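"""CSV serialization of cohorts and score tables.

One row per patient-timepoint; header uses the snapshot field names; enums are
lowercase strings; an empty cell means missing.  Every output carries a
provenance comment header (tool version, seed, config hash); readers skip
``#`` comment lines.
"""

from __future__ import annotations

import csv
import hashlib
from pathlib import Path
from typing import Iterable, List, Optional, Sequence

import pandas as pd

from . import __version__
from .errors import CohortParseError, MsofaError, ValidationError
from .scoring import score_panel
from .types import (
    ORGAN_ORDER,
    BleedingSign,
    Cause,
    CohortRecord,
    Instrument,
    JaundiceGrade,
    Outcome,
    PhysiologySnapshot,
    Sex,
    Timepoint,
)

__all__ = [
    "COHORT_COLUMNS",
    "provenance_line",
    "read_cohort_csv",
    "write_cohort_csv",
    "score_cohort",
    "write_scores_csv",
    "read_scores_csv",
]

_DEMO_COLUMNS = (
    "patient_id",
    "timepoint",
    "age",
    "sex",
    "cause",
    "outcome",
    "ventilation_days",
    "icu_days",
    "hospital_days",
)
_SNAPSHOT_COLUMNS = (
    "spo2",
    "fio2",
    "on_respiratory_support",
    "bleeding_sign",
    "map",
    "dopamine",
    "dobutamine",
    "epinephrine",
    "norepinephrine",
    "jaundice",
    "gcs",
    "urine_output_per_kg",
    "pao2",
    "platelets",
    "bilirubin",
    "creatinine",
    "urine_output_daily",
)
COHORT_COLUMNS = _DEMO_COLUMNS + _SNAPSHOT_COLUMNS

_OPTIONAL_FLOATS = {
    "ventilation_days",
    "icu_days",
    "hospital_days",
    "pao2",
    "platelets",
    "bilirubin",
    "creatinine",
    "urine_output_daily",
}


def provenance_line(seed: Optional[int] = None, config_items: Optional[dict] = None) -> str:
    """Comment line recording tool version, seed and a short config hash."""
    items = dict(config_items or {})
    if seed is not None:
        items["seed"] = seed
    blob = ";".join(f"{k}={items[k]}" for k in sorted(items))
    sha = hashlib.sha256(blob.encode()).hexdigest()[:12]
    parts = [f"# msofa {__version__}"]
    if seed is not None:
        parts.append(f"seed={seed}")
    parts.append(f"config_sha={sha}")
    return " ".join(parts)


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "true" if value else "false"
    if isinstance(value, (Outcome, Sex, Cause, BleedingSign, JaundiceGrade, Instrument)):
        return value.value
    if isinstance(value, Timepoint):
        return value.value
    return repr(value) if isinstance(value, float) else str(value)


def write_cohort_csv(
    records: Sequence[CohortRecord],
    path,
    seed: Optional[int] = None,
    config_items: Optional[dict] = None,
) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(provenance_line(seed, config_items) + "\n")
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for rec in records:
            for tp in sorted(rec.snapshots, key=lambda t: t.value):
                snap = rec.snapshots[tp]
                row = [
                    rec.patient_id,
                    tp.value,
                    _fmt(rec.age),
                    _fmt(rec.sex),
                    _fmt(rec.cause),
                    _fmt(rec.outcome),
                    _fmt(rec.ventilation_days),
                    _fmt(rec.icu_days),
                    _fmt(rec.hospital_days),
                ]
                row += [_fmt(getattr(snap, col)) for col in _SNAPSHOT_COLUMNS]
                writer.writerow(row)


def _parse_float(token: str, row: int, col: str, problems: list, optional=False):
    if token == "":
        if optional:
            return None
        problems.append(f"row {row}: column {col!r} is empty but required")
        return None
    try:
        return float(token)
    except ValueError:
        problems.append(f"row {row}: column {col!r}: non-numeric value {token!r}")
        return None


def _parse_enum(token: str, enum_cls, row: int, col: str, problems: list):
    try:
        return enum_cls(token)
    except ValueError:
        valid = ", ".join(e.value for e in enum_cls)
        problems.append(f"row {row}: column {col!r}: bad token {token!r} (expected one of: {valid})")
        return None


def read_cohort_csv(path) -> List[CohortRecord]:
    """Parse a cohort CSV into typed records; reports every problem with its
    row and column before raising."""
    path = Path(path)
    problems: list = []
    with path.open(newline="") as fh:
        rows = [
            (lineno, r)
            for lineno, r in enumerate(csv.reader(fh), start=1)
            if r and not r[0].startswith("#")
        ]
    if not rows:
        raise CohortParseError("empty file: no header or data rows")
    header = rows[0][1]
    unknown = set(header) - set(COHORT_COLUMNS)
    if unknown:
        raise CohortParseError([f"unknown column(s): {', '.join(sorted(unknown))}"])
    missing_cols = set(COHORT_COLUMNS) - set(header)
    if missing_cols:
        raise CohortParseError([f"missing column(s): {', '.join(sorted(missing_cols))}"])
    if len(rows) == 1:
        raise CohortParseError("empty cohort: header present but no data rows")

    idx = {c: header.index(c) for c in header}
    records: dict = {}
    order: list = []
    for rownum, row in rows[1:]:
        cell = lambda c: row[idx[c]].strip()
        pid = cell("patient_id")
        if not pid:
            problems.append(f"row {rownum}: empty patient_id")
            continue
        tp = _parse_enum(cell("timepoint"), Timepoint, rownum, "timepoint", problems)
        sex = _parse_enum(cell("sex"), Sex, rownum, "sex", problems)
        cause = _parse_enum(cell("cause"), Cause, rownum, "cause", problems)
        outcome = _parse_enum(cell("outcome"), Outcome, rownum, "outcome", problems)
        bleeding = _parse_enum(cell("bleeding_sign"), BleedingSign, rownum, "bleeding_sign", problems)
        jaundice = _parse_enum(cell("jaundice"), JaundiceGrade, rownum, "jaundice", problems)

        age = _parse_float(cell("age"), rownum, "age", problems)
        support_tok = cell("on_respiratory_support")
        if support_tok in ("true", "false"):
            support = support_tok == "true"
        else:
            problems.append(
                f"row {rownum}: column 'on_respiratory_support': bad token {support_tok!r} "
                "(expected true/false)"
            )
            support = None

        floats = {}
        for col in _SNAPSHOT_COLUMNS:
            if col in ("on_respiratory_support", "bleeding_sign", "jaundice", "gcs"):
                continue
            floats[col] = _parse_float(cell(col), rownum, col, problems, optional=col in _OPTIONAL_FLOATS)
        gcs_tok = cell("gcs")
        try:
            gcs = int(gcs_tok)
        except ValueError:
            problems.append(f"row {rownum}: column 'gcs': non-integer value {gcs_tok!r}")
            gcs = None
        optional_demo = {
            col: _parse_float(cell(col), rownum, col, problems, optional=True)
            for col in ("ventilation_days", "icu_days", "hospital_days")
        }

        if any(v is None for v in (tp, sex, cause, outcome, bleeding, jaundice, age, support, gcs)):
            continue
        required = {
            c: floats[c]
            for c in _SNAPSHOT_COLUMNS
            if c not in _OPTIONAL_FLOATS and c not in ("on_respiratory_support", "bleeding_sign", "jaundice", "gcs")
        }
        if any(v is None for v in required.values()):
            continue
        try:
            snap = PhysiologySnapshot(
                patient_id=pid,
                timepoint=tp,
                on_respiratory_support=support,
                bleeding_sign=bleeding,
                jaundice=jaundice,
                gcs=gcs,
                **floats,
            )
        except ValidationError as exc:
            problems.append(f"row {rownum}: {exc}")
            continue
        if pid not in records:
            records[pid] = CohortRecord(
                patient_id=pid, age=age, sex=sex, cause=cause, outcome=outcome,
                snapshots={}, **optional_demo,
            )
            order.append(pid)
        if tp in records[pid].snapshots:
            problems.append(f"row {rownum}: duplicate timepoint {tp.value} for patient {pid}")
            continue
        records[pid].snapshots[tp] = snap

    if problems:
        raise CohortParseError(problems)
    return [records[pid] for pid in order]


def score_cohort(
    records: Sequence[CohortRecord], instruments: Iterable[Instrument] = (Instrument.SOFA, Instrument.MSOFA)
) -> pd.DataFrame:
    """Score every snapshot with each instrument; long-format table with one
    row per patient-timepoint-instrument."""
    rows = []
    for rec in records:
        for tp in sorted(rec.snapshots, key=lambda t: t.value):
            snap = rec.snapshots[tp]
            for inst in instruments:
                panel = score_panel(snap, inst)
                row = {
                    "patient_id": rec.patient_id,
                    "timepoint": tp.value,
                    "instrument": Instrument(inst).value,
                    "outcome": rec.outcome.value,
                }
                row.update({organ.value: getattr(panel, organ.value) for organ in ORGAN_ORDER})
                row["total"] = panel.total
                rows.append(row)
    if not rows:
        raise MsofaError("no scorable records in cohort")
    return pd.DataFrame(rows)


def write_scores_csv(scores: pd.DataFrame, path, seed=None, config_items=None) -> None:
    path = Path(path)
    with path.open("w", newline="") as fh:
        fh.write(provenance_line(seed, config_items) + "\n")
        scores.to_csv(fh, index=False)


def read_scores_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
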