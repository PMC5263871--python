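"""Reading and writing the tabular outcome-measure database.

The on-disk dialect is comma-separated UTF-8 text with a mandatory header
row. A column-mapping configuration (canonical field name -> source header)
absorbs arbitrary source layouts, so an externally deposited database can be
ingested without code changes. Rows that fail to parse or validate are
collected into a rejects report; the run continues with the parseable rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import pandas as pd
import yaml

from .records import (
    EnumLabelError,
    OutcomeMeasure,
    normalize_label,
    record_fields,
    validate_record,
)

MANDATORY_COLUMNS = ("study_id", "metric", "x_start", "x_end", "x_ref", "t_years")

_NUMERIC_FIELDS = {
    "x_start": float,
    "x_end": float,
    "x_ref": float,
    "t_years": float,
    "variance": float,
    "n_recovery_sites": int,
    "n_reference_sites": int,
    "area_km2": float,
    "disturbance_duration_years": float,
}
_ENUM_FIELDS = ("metric", "submetric", "ecosystem", "disturbance")
_LABEL_FIELDS = ("organism", "koppen")


class SchemaError(ValueError):
    """The input file is missing a mandatory column."""


@dataclass
class Reject:
    """A row that could not be turned into a valid record."""

    row: int  # 1-based data-row number (header not counted)
    reasons: list[str]


@dataclass
class ReadResult:
    """Parseable records plus the rejects report for one input file."""

    records: list[OutcomeMeasure]
    rejects: list[Reject] = field(default_factory=list)

    @property
    def n_input_rows(self) -> int:
        return len(self.records) + len(self.rejects)


def load_mapping_config(path: Union[str, Path]) -> dict:
    """Load a YAML mapping config: ``columns`` (canonical -> source header)
    and optional ``synonyms`` (label -> canonical enum value)."""
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    return {"columns": cfg.get("columns", {}), "synonyms": cfg.get("synonyms", {})}


def _is_missing(v: object) -> bool:
    return v is None or (isinstance(v, float) and pd.isna(v)) or (
        isinstance(v, str) and v.strip() == ""
    )


def read_database(
    path: Union[str, Path],
    mapping: Optional[dict[str, str]] = None,
    synonyms: Optional[dict[str, str]] = None,
) -> ReadResult:
    """Read a CSV database of outcome measures.

    Parameters
    ----------
    path
        CSV file (comma, UTF-8, header row mandatory).
    mapping
        Canonical field name -> source header. Unmapped canonical fields fall
        back to their own name. The six mandatory columns must resolve.
    synonyms
        Extra label -> canonical-enum entries merged over the built-in table.

    Returns
    -------
    ReadResult
        All parseable rows (each carrying its 1-based ``source_line``) and a
        rejects report naming every dropped row and why.
    """
    mapping = dict(mapping or {})
    raw = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    colmap = {f: mapping.get(f, f) for f in record_fields() if f != "source_line"}
    for f in MANDATORY_COLUMNS:
        if colmap[f] not in raw.columns:
            raise SchemaError(f"missing mandatory column {colmap[f]!r} (for field {f!r})")

    records: list[OutcomeMeasure] = []
    rejects: list[Reject] = []
    for i, (_, row) in enumerate(raw.iterrows(), start=1):
        reasons: list[str] = []
        kw: dict = {"source_line": i}
        for f, src in colmap.items():
            if src not in raw.columns:
                continue
            cell = row[src]
            if f in _NUMERIC_FIELDS:
                if _is_missing(cell):
                    if f in MANDATORY_COLUMNS:
                        reasons.append(f"{f}: missing value")
                    continue
                try:
                    kw[f] = _NUMERIC_FIELDS[f](float(cell))
                except (TypeError, ValueError):
                    reasons.append(f"{f}: unparseable numeric cell {cell!r}")
            elif f in _ENUM_FIELDS:
                if _is_missing(cell):
                    if f == "metric":
                        reasons.append("metric: missing value")
                    elif f == "submetric":
                        kw[f] = "none"
                    continue
                try:
                    kw[f] = normalize_label(f, cell, synonyms)
                except EnumLabelError as e:
                    reasons.append(str(e))
            elif f in _LABEL_FIELDS:
                if not _is_missing(cell):
                    kw[f] = str(cell)
            else:  # study_id / outcome_id: opaque identifiers
                if not _is_missing(cell):
                    kw[f] = str(cell)
        if "study_id" not in kw:
            reasons.append("study_id: missing value")
        kw.setdefault("outcome_id", f"row{i}")
        if not reasons:
            rec = OutcomeMeasure(**kw)
            reasons = validate_record(rec)
            if not reasons:
                records.append(rec)
        if reasons:
            rejects.append(Reject(row=i, reasons=reasons))
    return ReadResult(records=records, rejects=rejects)


def records_to_frame(records: Iterable[OutcomeMeasure]) -> pd.DataFrame:
    """Tabulate records in the canonical column order."""
    cols = record_fields()
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in records], columns=cols)


def write_database(records: Sequence[OutcomeMeasure], path: Union[str, Path]) -> None:
    """Write records as a canonical-schema CSV (readable by read_database)."""
    write_results(records_to_frame(records).drop(columns=["source_line"]), path)


def write_results(rows: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a result table as UTF-8 CSV with header, full numeric precision.

    Floats are written with ``repr`` precision so a write/read roundtrip
    preserves values exactly. An empty table is a contract violation.
    """
    if rows is None or len(rows) == 0:
        raise ValueError("write_results: refusing to write an empty table")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    rows.to_csv(path, index=False, encoding="utf-8")
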