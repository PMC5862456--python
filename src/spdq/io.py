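"""CSV cohort reading/writing and JSON report serialization.

One CSV row per respondent; empty cells are missing responses.  Malformed
cells are reported with their row number (1-based, excluding the header)
and column, and reading fails loudly rather than silently coercing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import pandas as pd

from .instruments import (
    COURSE_PATTERNS,
    GROUP_LABELS,
    SENSORY_ITEMS,
    QuestionnaireRecord,
    score_instrument,
    score_pdq,
    SPDQ,
    SF_SPDQ,
)

__all__ = [
    "CSV_COLUMNS",
    "ParseReport",
    "CohortFormatError",
    "read_cohort",
    "records_to_frame",
    "write_cohort",
    "score_cohort",
    "write_report",
    "read_report",
]

_NRS_COLUMNS = ("nrs_current", "nrs_worst_4w", "nrs_avg_4w")
CSV_COLUMNS: tuple[str, ...] = SENSORY_ITEMS + (
    "course_pattern",
    "radiating",
) + _NRS_COLUMNS + ("group",)

#: Columns score_cohort appends; tolerated (and ignored) on input so scored
#: files can be re-read.
_OUTPUT_COLUMNS = (
    "pdq_total",
    "pdq_band",
    "spdq_total",
    "spdq_class",
    "sf_spdq_total",
    "sf_spdq_class",
    "complete",
)


class CohortFormatError(ValueError):
    """Input CSV violates the cohort schema; carries all cell-level messages."""

    def __init__(self, problems: Sequence[str]):
        self.problems = list(problems)
        super().__init__("\n".join(self.problems))


@dataclass
class ParseReport:
    n_rows: int = 0
    n_complete: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {"n_rows": self.n_rows, "n_complete": self.n_complete, "warnings": self.warnings}


def _parse_int(raw: str, lo: int, hi: int, row: int, col: str, problems: list[str]) -> int | None:
    try:
        v = int(raw)
    except ValueError:
        problems.append(f"row {row}, column {col!r}: not an integer: {raw!r}")
        return None
    if not lo <= v <= hi:
        problems.append(f"row {row}, column {col!r}: value {v} outside [{lo}, {hi}]")
        return None
    return v


def read_cohort(path: str | Path) -> tuple[list[QuestionnaireRecord], ParseReport]:
    """Read a cohort CSV into typed records.

    Raises :class:`CohortFormatError` listing every offending cell (row and
    column) if any value is malformed, and on unknown columns.
    """
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    unknown = [c for c in frame.columns if c not in CSV_COLUMNS + _OUTPUT_COLUMNS]
    if unknown:
        raise CohortFormatError([f"unknown column(s): {', '.join(map(repr, unknown))}"])

    problems: list[str] = []
    report = ParseReport(n_rows=len(frame))
    records: list[QuestionnaireRecord] = []
    for idx, row in frame.iterrows():
        rownum = int(idx) + 1
        kwargs: dict = {}
        for col in SENSORY_ITEMS:
            raw = str(row[col]).strip() if col in frame.columns else ""
            kwargs[col] = None if raw == "" else _parse_int(raw, 0, 5, rownum, col, problems)
        for col in _NRS_COLUMNS:
            raw = str(row[col]).strip() if col in frame.columns else ""
            kwargs[col] = None if raw == "" else _parse_int(raw, 0, 10, rownum, col, problems)
        raw = str(row["course_pattern"]).strip() if "course_pattern" in frame.columns else ""
        if raw == "":
            kwargs["course_pattern"] = None
        elif raw in COURSE_PATTERNS:
            kwargs["course_pattern"] = raw
        else:
            problems.append(
                f"row {rownum}, column 'course_pattern': unknown category {raw!r} "
                f"(expected one of {', '.join(COURSE_PATTERNS)})"
            )
            kwargs["course_pattern"] = None
        raw = str(row["radiating"]).strip().lower() if "radiating" in frame.columns else ""
        if raw == "":
            kwargs["radiating"] = None
        elif raw in ("yes", "no"):
            kwargs["radiating"] = raw == "yes"
        else:
            problems.append(f"row {rownum}, column 'radiating': expected yes/no, got {raw!r}")
            kwargs["radiating"] = None
        raw = str(row["group"]).strip() if "group" in frame.columns else ""
        if raw == "":
            kwargs["group_label"] = None
        elif raw in GROUP_LABELS:
            kwargs["group_label"] = raw
        else:
            problems.append(
                f"row {rownum}, column 'group': expected NeP-SD or NocP, got {raw!r}"
            )
            kwargs["group_label"] = None
        if not problems:
            rec = QuestionnaireRecord(**kwargs)
            records.append(rec)
            if not rec.missing_items():
                report.n_complete += 1
    if problems:
        raise CohortFormatError(problems)
    return records, report


def records_to_frame(records: Sequence[QuestionnaireRecord]) -> pd.DataFrame:
    """Records back to the cohort CSV schema (missing -> empty cell)."""
    rows = []
    for r in records:
        row = {col: getattr(r, col) for col in SENSORY_ITEMS + _NRS_COLUMNS}
        row["course_pattern"] = r.course_pattern
        row["radiating"] = None if r.radiating is None else ("yes" if r.radiating else "no")
        row["group"] = r.group_label
        rows.append(row)
    frame = pd.DataFrame(rows, columns=list(CSV_COLUMNS))
    for col in SENSORY_ITEMS + _NRS_COLUMNS:
        frame[col] = frame[col].astype("Int64")
    return frame


def write_cohort(records: Sequence[QuestionnaireRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, index=False)


def score_cohort(records: Sequence[QuestionnaireRecord]) -> pd.DataFrame:
    """Cohort rows plus PD-Q / SPDQ / SF-SPDQ totals and classifications.

    Incomplete scores stay empty; ``complete`` flags rows with all nine
    scored items present.
    """
    frame = records_to_frame(records)
    pdq, spdq, sf = [], [], []
    for r in records:
        pdq.append(score_pdq(r))
        spdq.append(score_instrument(r, SPDQ))
        sf.append(score_instrument(r, SF_SPDQ))
    frame["pdq_total"] = pd.array([s.total for s in pdq], dtype="Int64")
    frame["pdq_band"] = [s.classification for s in pdq]
    frame["spdq_total"] = pd.array([s.total for s in spdq], dtype="Int64")
    frame["spdq_class"] = [s.classification for s in spdq]
    frame["sf_spdq_total"] = pd.array([s.total for s in sf], dtype="Int64")
    frame["sf_spdq_class"] = [s.classification for s in sf]
    frame["complete"] = [not r.missing_items() for r in records]
    return frame


def write_report(payload: dict, path: str | Path, fmt: str = "json") -> None:
    """Serialize a report with deterministic field order."""
    path = Path(path)
    if fmt == "json":
        path.write_text(json.dumps(payload, indent=2, sort_keys=False) + "\n")
    elif fmt == "csv":
        flat = _flatten(payload)
        pd.DataFrame([flat]).to_csv(path, index=False)
    else:
        raise ValueError(f"unknown report format {fmt!r}")


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())


def _flatten(d: dict, prefix: str = "") -> dict:
    out: dict = {}
    for k, v in d.items():
        key = f"{prefix}{k}"
        if isinstance(v, dict):
            out.update(_flatten(v, key + "."))
        else:
            out[key] = v
    return out
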