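"""Read and write the per-pregnancy cohort CSV and result tables.

Cohort schema (header mandatory, comma-separated, UTF-8): one row per
pregnancy with the columns in :data:`COHORT_COLUMNS`.  Booleans are encoded
0/1, missing values as empty fields, history variables as
``first_child``/``no``/``yes``, and ethnicity by its lower-case enum name.
Unknown ethnicity strings fall back to ``other`` with a warning, so cohorts
labelled with a finer ethnic classification still load.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .diagnosis import Thresholds, DEFAULT_THRESHOLDS, round_reported
from .model import (
    Ethnicity,
    GlucoseTriplet,
    HistoryStatus,
    OUTCOME_FIELDS,
    OutcomeRecord,
    RowError,
    SchemaError,
    WomanRecord,
)

COHORT_COLUMNS: tuple[str, ...] = (
    "id",
    "age_years",
    "bmi_pre",
    "early_fpg_mmol_l",
    "fpg_mmol_l",
    "pg1h_mmol_l",
    "pg2h_mmol_l",
    "ga_ogtt_weeks",
    "history_hip",
    "history_macrosomia",
    "history_fetal_death",
    "family_history_diabetes",
    "ethnicity",
    "singleton",
    "prior_diabetes",
    "prior_bariatric_surgery",
) + OUTCOME_FIELDS

_FLOAT_COLUMNS = (
    "age_years",
    "bmi_pre",
    "early_fpg_mmol_l",
    "fpg_mmol_l",
    "pg1h_mmol_l",
    "pg2h_mmol_l",
    "ga_ogtt_weeks",
)


@dataclass(frozen=True)
class RowWarning:
    line: int  # 1-based data-row number (header is line 0)
    record_id: str
    message: str


def _parse_bool(raw, line: int, column: str) -> Optional[bool]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return None
    s = str(raw).strip().lower()
    if s in ("1", "true", "yes"):
        return True
    if s in ("0", "false", "no"):
        return False
    raise RowError(f"row {line}: cannot parse boolean {column}={raw!r}")


def _parse_float(raw, line: int, column: str) -> Optional[float]:
    if raw is None or raw == "":
        return None
    try:
        v = float(raw)
    except (TypeError, ValueError):
        raise RowError(f"row {line}: cannot parse numeric {column}={raw!r}") from None
    return None if np.isnan(v) else v


def _parse_history(raw, line: int, column: str) -> Optional[HistoryStatus]:
    if raw is None or (isinstance(raw, float) and np.isnan(raw)) or raw == "":
        return None
    try:
        return HistoryStatus(str(raw).strip().lower())
    except ValueError:
        raise RowError(
            f"row {line}: {column}={raw!r} is not one of first_child/no/yes"
        ) from None


def _validate_record(r: WomanRecord, thresholds: Thresholds) -> list[str]:
    """Invariant checks on one parsed record; returns violation messages."""
    problems: list[str] = []
    for name, v in (
        ("early_fpg_mmol_l", r.early_fpg),
        ("fpg_mmol_l", r.ogtt.fpg),
        ("pg1h_mmol_l", r.ogtt.pg1h),
        ("pg2h_mmol_l", r.ogtt.pg2h),
    ):
        if v is not None and not (1.0 < v < 30.0):
            problems.append(f"{name}={v:g} outside plausible range (1, 30) mmol/L")
    ga = r.ogtt.ga_weeks
    if ga is not None and not (thresholds.ga_min <= ga <= thresholds.ga_max):
        problems.append(
            f"ga_ogtt_weeks={ga:g} outside the eligible "
            f"{thresholds.ga_min:g}-{thresholds.ga_max:g} WG window"
        )
    if r.age_years is not None and not (
        thresholds.age_min <= r.age_years <= thresholds.age_max
    ):
        problems.append(
            f"age_years={r.age_years:g} outside the eligible "
            f"{thresholds.age_min:g}-{thresholds.age_max:g} range"
        )
    if r.bmi_pre is not None and not (10.0 < r.bmi_pre < 80.0):
        problems.append(f"bmi_pre={r.bmi_pre:g} outside plausible range (10, 80)")
    if r.early_fpg is not None and round_reported(r.early_fpg) >= thresholds.early_fpg_cutoff:
        problems.append(
            f"early_fpg_mmol_l={r.early_fpg:g} at or above the "
            f"{thresholds.early_fpg_cutoff:g} mmol/L early-HIP eligibility bound"
        )
    return problems


def _row_to_record(
    row: dict, line: int, warnings_out: list[RowWarning]
) -> WomanRecord:
    rid = str(row["id"])
    eth_raw = row.get("ethnicity")
    ethnicity: Optional[Ethnicity]
    if eth_raw is None or (isinstance(eth_raw, float) and np.isnan(eth_raw)) or eth_raw == "":
        ethnicity = None
    else:
        try:
            ethnicity = Ethnicity(str(eth_raw).strip().lower())
        except ValueError:
            ethnicity = Ethnicity.OTHER
            warnings_out.append(
                RowWarning(line, rid, f"unknown ethnicity {eth_raw!r} mapped to 'other'")
            )
    floats = {c: _parse_float(row.get(c), line, c) for c in _FLOAT_COLUMNS}
    outcome_kwargs = {c: _parse_bool(row.get(c), line, c) for c in OUTCOME_FIELDS}
    return WomanRecord(
        id=rid,
        age_years=floats["age_years"],
        bmi_pre=floats["bmi_pre"],
        early_fpg=floats["early_fpg_mmol_l"],
        ogtt=GlucoseTriplet(
            fpg=floats["fpg_mmol_l"],
            pg1h=floats["pg1h_mmol_l"],
            pg2h=floats["pg2h_mmol_l"],
            ga_weeks=floats["ga_ogtt_weeks"],
        ),
        history_hip=_parse_history(row.get("history_hip"), line, "history_hip"),
        history_macrosomia=_parse_history(
            row.get("history_macrosomia"), line, "history_macrosomia"
        ),
        history_fetal_death=_parse_history(
            row.get("history_fetal_death"), line, "history_fetal_death"
        ),
        family_history_diabetes=_parse_bool(
            row.get("family_history_diabetes"), line, "family_history_diabetes"
        ),
        ethnicity=ethnicity,
        singleton=_parse_bool(row.get("singleton"), line, "singleton"),
        prior_diabetes=_parse_bool(row.get("prior_diabetes"), line, "prior_diabetes"),
        prior_bariatric_surgery=_parse_bool(
            row.get("prior_bariatric_surgery"), line, "prior_bariatric_surgery"
        ),
        outcomes=OutcomeRecord(**outcome_kwargs),
    )


def read_cohort(
    path: str | Path,
    strict: bool = False,
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[WomanRecord], list[RowWarning]]:
    """Read a cohort CSV into ``WomanRecord`` objects.

    Header matching is case-insensitive.  In strict mode any invariant
    violation raises :class:`RowError`; otherwise the offending row is still
    returned and the violation reported in the warning list.

    Raises
    ------
    SchemaError
        If a mandatory column is missing.
    RowError
        On unparseable values (always) or invariant violations (strict).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    df.columns = [c.strip().lower() for c in df.columns]
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    records: list[WomanRecord] = []
    warns: list[RowWarning] = []
    for i, row in enumerate(df.to_dict("records"), start=1):
        record = _row_to_record(row, i, warns)
        problems = _validate_record(record, thresholds)
        if problems:
            if strict:
                raise RowError(f"row {i} (id={record.id!r}): " + "; ".join(problems))
            for msg in problems:
                warns.append(RowWarning(i, record.id, msg))
        records.append(record)
    return records, warns


def _fmt_bool(v: Optional[bool]) -> str:
    return "" if v is None else str(int(v))


def _fmt_float(v: Optional[float]) -> str:
    return "" if v is None else repr(float(v))


def cohort_to_dataframe(records: Sequence[WomanRecord]) -> pd.DataFrame:
    """Serialize records to a string DataFrame in the documented schema."""
    rows = []
    for r in records:
        row = {
            "id": r.id,
            "age_years": _fmt_float(r.age_years),
            "bmi_pre": _fmt_float(r.bmi_pre),
            "early_fpg_mmol_l": _fmt_float(r.early_fpg),
            "fpg_mmol_l": _fmt_float(r.ogtt.fpg),
            "pg1h_mmol_l": _fmt_float(r.ogtt.pg1h),
            "pg2h_mmol_l": _fmt_float(r.ogtt.pg2h),
            "ga_ogtt_weeks": _fmt_float(r.ogtt.ga_weeks),
            "history_hip": r.history_hip.value if r.history_hip else "",
            "history_macrosomia": r.history_macrosomia.value if r.history_macrosomia else "",
            "history_fetal_death": r.history_fetal_death.value if r.history_fetal_death else "",
            "family_history_diabetes": _fmt_bool(r.family_history_diabetes),
            "ethnicity": r.ethnicity.value if r.ethnicity else "",
            "singleton": _fmt_bool(r.singleton),
            "prior_diabetes": _fmt_bool(r.prior_diabetes),
            "prior_bariatric_surgery": _fmt_bool(r.prior_bariatric_surgery),
        }
        for name in OUTCOME_FIELDS:
            row[name] = _fmt_bool(getattr(r.outcomes, name))
        rows.append(row)
    return pd.DataFrame(rows, columns=list(COHORT_COLUMNS))


def write_cohort(records: Sequence[WomanRecord], path: str | Path) -> None:
    """Write records as a schema-conformant cohort CSV."""
    if not records:
        raise ValueError("refusing to write an empty cohort")
    cohort_to_dataframe(records).to_csv(path, index=False)


def write_results(table: pd.DataFrame, path: str | Path, format: str = "csv") -> None:
    """Write a result table as CSV or JSON.

    Columns whose name ends in ``_pct`` hold percentages and are rendered to
    one decimal, the convention of the published tables; every other numeric
    column keeps full precision so a round-trip read reproduces values to
    1e-9 or better.
    """
    if table is None or len(table) == 0:
        raise ValueError("refusing to write an empty result table")
    if format not in ("csv", "json"):
        raise ValueError("format must be 'csv' or 'json'")
    out = table.copy()
    for col in out.columns:
        if str(col).endswith("_pct"):
            out[col] = out[col].map(lambda v: v if pd.isna(v) else float(f"{v:.1f}"))
    if format == "csv":
        out.to_csv(path, index=False)
    else:
        out.to_json(path, orient="records", indent=2)


def read_results(path: str | Path, format: str = "csv") -> pd.DataFrame:
    if format == "csv":
        return pd.read_csv(path)
    return pd.read_json(path)


def filter_eligible(
    records: Sequence[WomanRecord],
    thresholds: Thresholds = DEFAULT_THRESHOLDS,
) -> tuple[list[WomanRecord], list[tuple[str, tuple[str, ...]]]]:
    """Split a cohort into eligible records and (id, reasons) exclusions."""
    from .diagnosis import check_eligibility

    kept: list[WomanRecord] = []
    excluded: list[tuple[str, tuple[str, ...]]] = []
    for r in records:
        verdict = check_eligibility(r, thresholds)
        if verdict.eligible:
            kept.append(r)
        else:
            excluded.append((r.id, verdict.reasons))
    return kept, excluded
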