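"""Cohort table I/O and run manifests.

The cohort file is a delimited table (CSV, or TSV for ``.tsv``/``.txt``
paths) with one row per subject:

    subject_id, ccl3_pg_ml, il8_pg_ml, hspa1b_pg_ml, gzmb_pg_ml, mmp8_pg_ml,
    age_years, died_28d [, prism, picu_los_days, max_organ_failures,
    organ_failures_ge2_day7, comorbidity, immune_suppression]

Biomarker concentrations are pg/ml, age is decimal years, and boolean
columns accept 0/1 or true/false.  The clinical-course columns are
optional; missing individual values are written/read as empty cells.
Lines starting with ``#`` are comments (the writer records the generator
seed there).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from datetime import datetime, timezone
from pathlib import Path
from typing import Optional, Sequence

import pandas as pd

from . import __version__
from .cohort import CohortRecord
from .tree import BIOMARKERS, BiomarkerProfile, ProfileError, RiskAssignment

__all__ = [
    "REQUIRED_COLUMNS",
    "OPTIONAL_COLUMNS",
    "CohortFormatError",
    "read_cohort",
    "write_cohort",
    "write_assignments",
    "RunManifest",
]

_BIOMARKER_COLS = {var: f"{var}_pg_ml" for var in BIOMARKERS}
REQUIRED_COLUMNS = (
    "subject_id",
    *(_BIOMARKER_COLS[v] for v in BIOMARKERS),
    "age_years",
    "died_28d",
)
OPTIONAL_COLUMNS = (
    "prism",
    "picu_los_days",
    "max_organ_failures",
    "organ_failures_ge2_day7",
    "comorbidity",
    "immune_suppression",
)

_TRUE = {"1", "true", "yes", "died"}
_FALSE = {"0", "false", "no", "survived"}


class CohortFormatError(ValueError):
    """Raised for schema or value errors in a cohort file."""


def _sep_for(path: Path) -> str:
    return "\t" if path.suffix.lower() in (".tsv", ".txt") else ","


def _parse_bool(value, row: int, column: str) -> bool:
    text = str(value).strip().lower()
    if text in _TRUE:
        return True
    if text in _FALSE:
        return False
    raise CohortFormatError(f"row {row}, column {column!r}: cannot parse boolean {value!r}")


def _parse_float(value, row: int, column: str) -> float:
    try:
        x = float(value)
    except (TypeError, ValueError):
        raise CohortFormatError(
            f"row {row}, column {column!r}: non-numeric value {value!r}"
        ) from None
    if not math.isfinite(x):
        raise CohortFormatError(f"row {row}, column {column!r}: non-finite value")
    return x


def _missing(value) -> bool:
    return value is None or (isinstance(value, float) and math.isnan(value)) or (
        isinstance(value, str) and value.strip() == ""
    )


def read_cohort(path) -> list[CohortRecord]:
    """Read and validate a cohort table; row numbers appear in error messages."""
    path = Path(path)
    frame = pd.read_csv(path, sep=_sep_for(path), comment="#", dtype=str)
    missing_cols = [c for c in REQUIRED_COLUMNS if c not in frame.columns]
    if missing_cols:
        raise CohortFormatError(f"missing required column(s): {', '.join(missing_cols)}")
    records: list[CohortRecord] = []
    for i, row in enumerate(frame.to_dict("records"), start=2):  # 1-based + header
        sid = str(row["subject_id"]).strip()
        if not sid or _missing(row["subject_id"]):
            raise CohortFormatError(f"row {i}: empty subject_id")
        values = {}
        for var in BIOMARKERS:
            values[var] = _parse_float(row[_BIOMARKER_COLS[var]], i, _BIOMARKER_COLS[var])
        values["age"] = _parse_float(row["age_years"], i, "age_years")
        try:
            profile = BiomarkerProfile(**values)
        except ProfileError as exc:
            raise CohortFormatError(f"row {i} (subject {sid}): {exc}") from None
        died = _parse_bool(row["died_28d"], i, "died_28d")

        def opt(column, parser):
            if column not in frame.columns or _missing(row[column]):
                return None
            return parser(row[column], i, column)

        records.append(
            CohortRecord(
                subject_id=sid,
                profile=profile,
                died_28d=died,
                prism=opt("prism", _parse_float),
                picu_los_days=opt("picu_los_days", _parse_float),
                max_organ_failures=(
                    None
                    if (v := opt("max_organ_failures", _parse_float)) is None
                    else int(v)
                ),
                organ_failures_ge2_day7=opt("organ_failures_ge2_day7", _parse_bool),
                comorbidity=opt("comorbidity", _parse_bool),
                immune_suppression=opt("immune_suppression", _parse_bool),
            )
        )
    if not records:
        raise CohortFormatError(f"{path}: no subject rows")
    return records


def _fmt(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return str(int(value))
    if isinstance(value, float):
        return repr(value)
    return str(value)


def write_cohort(records: Sequence[CohortRecord], path, seed: Optional[int] = None) -> None:
    """Write a cohort table (full float precision, round-trip safe)."""
    path = Path(path)
    sep = _sep_for(path)
    columns = list(REQUIRED_COLUMNS) + list(OPTIONAL_COLUMNS)
    with open(path, "w", encoding="utf-8") as out:
        if seed is not None:
            out.write(f"# generated by persevere {__version__}; seed={seed}\n")
        out.write(sep.join(columns) + "\n")
        for r in records:
            row = [
                r.subject_id,
                *(_fmt(r.profile.value_of(v)) for v in BIOMARKERS),
                _fmt(r.profile.age),
                _fmt(r.died_28d),
                _fmt(r.prism),
                _fmt(r.picu_los_days),
                _fmt(r.max_organ_failures),
                _fmt(r.organ_failures_ge2_day7),
                _fmt(r.comorbidity),
                _fmt(r.immune_suppression),
            ]
            out.write(sep.join(row) + "\n")


def write_assignments(assignments: Sequence[RiskAssignment], path) -> None:
    """Write the classification output table."""
    frame = pd.DataFrame(
        {
            "subject_id": [a.subject_id for a in assignments],
            "terminal_node": [a.terminal_node for a in assignments],
            "mortality_probability": [a.mortality_probability for a in assignments],
            "risk_class": [a.risk_class for a in assignments],
            "predicted_nonsurvivor": [int(a.predicted_nonsurvivor) for a in assignments],
        }
    )
    path = Path(path)
    frame.to_csv(path, sep=_sep_for(path), index=False)


@dataclass(frozen=True)
class RunManifest:
    """Provenance block embedded in every report."""

    command: str
    inputs: tuple[str, ...]
    tree_name: str
    cutoff: float
    conf: float
    seed: Optional[int] = None
    timestamp: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat(timespec="seconds")
    )
    version: str = __version__

    def to_dict(self) -> dict:
        return asdict(self)
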