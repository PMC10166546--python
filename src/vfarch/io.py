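"""Reading and writing visual-field tables (CSV and XLSX).

Two dialects are supported:

``s1``
    The package's canonical table layout: leading metadata columns
    (``patient_id, eye, visit_day, visit_type, fixation_loss_pct,
    false_pos_pct, false_neg_pct``), then the 52 total-deviation columns
    ``td_01 .. td_54`` with ``td_26`` and ``td_35`` absent (the two
    blind-spot points of the 54-point 24-2 grid), then ``md``.  This mirrors
    the layout of published clinic tables in which 52 contiguous columns hold
    the non-blind-spot test points and a final column holds MD.

``generic``
    Columns are located by (case-insensitive) name: any 52 columns starting
    with ``td`` in canonical order plus an ``md`` column; metadata columns are
    optional and defaulted when absent.

Rows whose TD cells are non-numeric, missing or out of range are rejected
individually and reported, never silently dropped.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import GRID
from .records import VisualFieldRecord


class VfFormatError(ValueError):
    """The table does not match the expected column layout."""


S1_METADATA_COLUMNS = (
    "patient_id",
    "eye",
    "visit_day",
    "visit_type",
    "fixation_loss_pct",
    "false_pos_pct",
    "false_neg_pct",
)


def td_column_names() -> list[str]:
    """The 52 TD column names, ``td_01 .. td_54`` minus the blind spot."""
    return [f"td_{i:02d}" for i in GRID.active_indices]


@dataclass
class ParseReport:
    path: str
    n_rows: int = 0
    n_ok: int = 0
    rejects: list[tuple[int, str]] = field(default_factory=list)

    @property
    def n_rejected(self) -> int:
        return len(self.rejects)

    def __str__(self) -> str:  # pragma: no cover - logging convenience
        msg = f"{self.path}: {self.n_ok}/{self.n_rows} rows parsed"
        if self.rejects:
            msg += f"; {self.n_rejected} rejected (first: row {self.rejects[0][0]}: {self.rejects[0][1]})"
        return msg


def _read_frame(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise OSError(f"input file not found: {path}")
    if path.suffix.lower() in (".xlsx", ".xlsm"):
        return pd.read_excel(path, engine="openpyxl")
    # round_trip parsing: decimal text written from repr() must come back
    # bit-exact, which the default fast float parser does not guarantee
    return pd.read_csv(path, float_precision="round_trip")


def _locate_td_columns(df: pd.DataFrame) -> list[str]:
    cols = [c for c in df.columns if str(c).lower().startswith("td")]
    if len(cols) != 52:
        raise VfFormatError(f"expected 52 TD columns, found {len(cols)}")
    return cols


def read_vf_table(
    path: str | Path, dialect: str = "s1"
) -> tuple[list[VisualFieldRecord], ParseReport]:
    """Read a VF table, returning well-formed records and a parse report.

    The TD columns are mapped left-to-right onto the canonical grid order.
    Malformed rows are rejected with a (row, reason) diagnostic in the report.
    """
    if dialect not in ("s1", "generic"):
        raise ValueError(f"unknown dialect {dialect!r}")
    df = _read_frame(path)
    df.columns = [str(c).strip().lower() for c in df.columns]
    td_cols = _locate_td_columns(df)
    if "md" not in df.columns:
        raise VfFormatError("missing required 'md' column")
    if dialect == "s1":
        missing = [c for c in S1_METADATA_COLUMNS[:4] if c not in df.columns]
        if missing:
            raise VfFormatError(f"s1 dialect missing metadata columns: {missing}")

    records: list[VisualFieldRecord] = []
    report = ParseReport(path=str(path), n_rows=len(df))
    for pos, (_, row) in enumerate(df.iterrows()):
        try:
            td = pd.to_numeric(row[td_cols], errors="raise").to_numpy(dtype=float)
        except (ValueError, TypeError):
            report.rejects.append((pos, "non-numeric TD cell"))
            continue
        try:
            md = float(row["md"])
            rel = {}
            for key in ("fixation_loss_pct", "false_pos_pct", "false_neg_pct"):
                val = row.get(key)
                rel[key] = None if val is None or (isinstance(val, float) and np.isnan(val)) else float(val)
            rec = VisualFieldRecord(
                patient_id=str(row.get("patient_id", f"row{pos}")),
                eye=str(row.get("eye", "OD")),
                visit_day=int(row.get("visit_day", 0)),
                visit_type=str(row.get("visit_type", "presentation")),
                td=td,
                md=md,
                **rel,
            )
        except (ValueError, TypeError) as exc:
            report.rejects.append((pos, str(exc)))
            continue
        records.append(rec)
        report.n_ok += 1
    return records, report


def records_to_frame(records: list[VisualFieldRecord]) -> pd.DataFrame:
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "patient_id": rec.patient_id,
            "eye": rec.eye,
            "visit_day": rec.visit_day,
            "visit_type": rec.visit_type,
            "fixation_loss_pct": rec.fixation_loss_pct,
            "false_pos_pct": rec.false_pos_pct,
            "false_neg_pct": rec.false_neg_pct,
        }
        for name, value in zip(td_column_names(), rec.td):
            row[name] = value
        row["md"] = rec.md
        rows.append(row)
    return pd.DataFrame(rows, columns=list(S1_METADATA_COLUMNS) + td_column_names() + ["md"])


def write_vf_table(
    records: list[VisualFieldRecord], path: str | Path, dialect: str = "s1"
) -> None:
    """Write records in the s1 layout.  CSV values use ``repr`` formatting so
    a read/write cycle round-trips TD values bit-exactly as decimal text."""
    if dialect != "s1":
        raise ValueError("only the s1 dialect is written")
    df = records_to_frame(records)
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() == ".xlsx":
        df.to_excel(path, index=False, engine="openpyxl")
    else:
        df.to_csv(path, index=False)
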