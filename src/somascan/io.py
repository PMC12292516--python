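"""Tabular readers and writers (CSV and XLSX).

Column mapping is explicit configuration, never header guessing: scanner
exports vary, and a silently swapped waist/hips column would corrupt the
body-fat formula invisibly.  Units are declared per column at ingest and
normalised to the package convention (cm everywhere, skinfolds mm, C7
landmark mm) in this module only; nothing downstream converts.

Invalid rows are quarantined with a row number and reason, never silently
dropped: ``rows in = rows accepted + rows rejected`` always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import pandas as pd

from .agreement import AgreementReport
from .errors import SchemaError
from .records import ManualAnthropometry, ScanAnthropometry, SomatotypeResult

MANUAL_COLUMNS = (
    "subject_id",
    "sex",
    "age",
    "height",
    "weight",
    "skinfold_triceps",
    "skinfold_subscapular",
    "skinfold_supraspinale",
    "skinfold_medial_calf",
    "girth_biceps",
    "girth_calf",
    "breadth_humerus",
    "breadth_femur",
)

SCAN_COLUMNS = (
    "subject_id",
    "sex",
    "age",
    "weight",
    "c7_height",
    "circ_waist",
    "circ_hips",
    "circ_neck",
    "girth_biceps",
    "girth_calf",
    "breadth_humerus",
    "breadth_femur",
)

#: native unit of each convertible column
_NATIVE_UNITS = {
    "c7_height": "mm",
    "skinfold_triceps": "mm",
    "skinfold_subscapular": "mm",
    "skinfold_supraspinale": "mm",
    "skinfold_medial_calf": "mm",
}
_CM_MM = {("cm", "mm"): 10.0, ("mm", "cm"): 0.1}


@dataclass(frozen=True)
class RejectedRow:
    row: int  # 0-based data-row index in the source table
    subject_id: str
    reason: str


@dataclass(frozen=True)
class DatasetTable:
    """An ingested table of validated records plus its reject log."""

    records: tuple[Union[ManualAnthropometry, ScanAnthropometry], ...]
    rejects: tuple[RejectedRow, ...]
    source: str
    kind: str  # "manual" | "scan"
    mapping: dict[str, str] = field(default_factory=dict)

    @property
    def n_input_rows(self) -> int:
        return len(self.records) + len(self.rejects)


def _convert(column: str, values: pd.Series, declared: str) -> pd.Series:
    native = _NATIVE_UNITS.get(column, "cm")
    if declared == native:
        return values
    key = (declared, native)
    if key not in _CM_MM:
        raise SchemaError(
            f"cannot convert column {column!r} from {declared!r} to {native!r}"
        )
    return values * _CM_MM[key]


def _read_frame(path: Path, fmt: Optional[str]) -> pd.DataFrame:
    if fmt is None:
        fmt = "xlsx" if path.suffix.lower() in (".xlsx", ".xlsm") else "csv"
    if fmt == "xlsx":
        return pd.read_excel(path, sheet_name=0)
    if fmt == "csv":
        return pd.read_csv(path)
    raise SchemaError(f"unknown table format {fmt!r}")


def read_table(
    path: str | Path,
    kind: str,
    *,
    format: Optional[str] = None,
    mapping: Optional[Mapping[str, str]] = None,
    units: Optional[Mapping[str, str]] = None,
) -> DatasetTable:
    """Read and validate a manual or scan anthropometry table.

    ``mapping`` maps canonical field names to source column headers (fields
    not listed are looked up under their canonical name).  ``units``
    declares the unit of convertible source columns (e.g. ``{"c7_height":
    "cm"}`` when the scanner exported cm); conversion to the package
    convention happens here and only here.

    Rows failing validation (including duplicate subject ids) are
    quarantined in the reject log with the row number and reason.
    """
    if kind not in ("manual", "scan"):
        raise SchemaError(f"kind must be 'manual' or 'scan', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise SchemaError(f"table not found: {path}")
    frame = _read_frame(path, format)
    required = MANUAL_COLUMNS if kind == "manual" else SCAN_COLUMNS
    mapping = dict(mapping or {})
    colmap = {canon: mapping.get(canon, canon) for canon in required}
    missing = [src for src in colmap.values() if src not in frame.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    if len(frame) == 0:
        raise SchemaError(f"{path}: table has a header but no data rows")

    data = frame[[colmap[c] for c in required]].copy()
    data.columns = list(required)
    for col, declared in (units or {}).items():
        if col in data.columns:
            data[col] = _convert(col, data[col], declared)

    cls = ManualAnthropometry if kind == "manual" else ScanAnthropometry
    records: list = []
    rejects: list[RejectedRow] = []
    seen: set[str] = set()
    for i, row in enumerate(data.to_dict(orient="records")):
        sid = str(row.get("subject_id", ""))
        try:
            if sid in seen:
                raise ValueError(f"duplicate subject_id {sid!r}")
            rec = cls(**{**row, "subject_id": sid})
            records.append(rec)
            seen.add(sid)
        except ValueError as e:
            rejects.append(RejectedRow(row=i, subject_id=sid, reason=_brief(e)))
    return DatasetTable(
        records=tuple(records),
        rejects=tuple(rejects),
        source=str(path),
        kind=kind,
        mapping=dict(colmap),
    )


def _brief(err: Exception) -> str:
    text = str(err)
    return text if len(text) < 400 else text[:397] + "..."


def records_frame(records: Sequence[Union[ManualAnthropometry, ScanAnthropometry]]) -> pd.DataFrame:
    """Records as a DataFrame in canonical column order."""
    if not records:
        return pd.DataFrame()
    kind = "manual" if isinstance(records[0], ManualAnthropometry) else "scan"
    cols = MANUAL_COLUMNS if kind == "manual" else SCAN_COLUMNS
    rows = [{c: getattr(r, c) for c in cols} for r in records]
    frame = pd.DataFrame(rows)
    frame["sex"] = frame["sex"].map(lambda s: s.value)
    return frame


def results_frame(results: Sequence[SomatotypeResult]) -> pd.DataFrame:
    """Somatotype results as a DataFrame.

    Components appear both raw (full precision, what statistics consume)
    and rounded to whole numbers (the conventional reporting form); BMI is
    additionally rendered to two decimals.
    """
    rows = []
    for r in results:
        rows.append(
            {
                "subject_id": r.subject_id,
                "pathway": r.pathway.value,
                "endomorphy": r.endomorphy,
                "mesomorphy": r.mesomorphy,
                "ectomorphy": r.ectomorphy,
                "endomorphy_rounded": round(r.endomorphy),
                "mesomorphy_rounded": round(r.mesomorphy),
                "ectomorphy_rounded": round(r.ectomorphy),
                "hwr": r.hwr,
                "bmi": r.bmi,
                "bmi_2dp": round(r.bmi, 2),
                "bf_percent": r.bf_percent,
                "chart_x": r.chart_x,
                "chart_y": r.chart_y,
                "category": r.category,
            }
        )
    return pd.DataFrame(rows)


def write_table(
    obj: Union[DatasetTable, Sequence, AgreementReport, pd.DataFrame],
    path: str | Path,
    *,
    format: Optional[str] = None,
) -> None:
    """Write records, somatotype results, a report or a frame to CSV/XLSX.

    CSV uses '.' decimals and 12-significant-digit floats so a write/read
    round trip preserves values to visual precision.
    """
    path = Path(path)
    if fmt_is_xlsx(path, format):
        fmt = "xlsx"
    else:
        fmt = "csv"
    if isinstance(obj, AgreementReport):
        obj.write(path)
        return
    if isinstance(obj, DatasetTable):
        frame = records_frame(obj.records)
    elif isinstance(obj, pd.DataFrame):
        frame = obj
    else:
        seq = list(obj)
        if seq and isinstance(seq[0], SomatotypeResult):
            frame = results_frame(seq)
        else:
            frame = records_frame(seq)
    try:
        if fmt == "xlsx":
            frame.to_excel(path, index=False)
        else:
            frame.to_csv(path, index=False, float_format="%.12g")
    except OSError as e:
        raise SchemaError(f"cannot write {path}: {e}") from e


def fmt_is_xlsx(path: Path, format: Optional[str]) -> bool:
    if format is not None:
        return format == "xlsx"
    return path.suffix.lower() == ".xlsx"
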