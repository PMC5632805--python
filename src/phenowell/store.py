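"""Tabular persistence and experiment bookkeeping.

Each analyzed image contributes one row — filename, acquisition date,
camera (x, y), then the column-wise list of per-well green areas — written
to XLSX (the platform's native output) and/or CSV.  Rows are joined with
the experiment design into records carrying time-from-start, treatment
label/code, plate type and table position, the structure all downstream
statistics consume.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import pandas as pd

from .plates import ExperimentDesign, standard_layout

__all__ = [
    "MeasurementRow",
    "ExperimentRecord",
    "FilenameError",
    "parse_filename",
    "format_filename",
    "export_table",
    "import_table",
    "build_experiment",
    "records_to_frame",
    "capacity_plan",
]

# <YYYYMMDD>T<HHMMSS>_x<int>_y<int>.png
_FILENAME_RE = re.compile(
    r"^(?P<date>\d{8})T(?P<time>\d{6})_x(?P<x>\d+)_y(?P<y>\d+)\.png$")


class FilenameError(ValueError):
    pass


@dataclass
class MeasurementRow:
    """One spreadsheet row: image identity plus its per-well areas."""

    filename: str
    acquisition_time: datetime
    camera_x: int
    camera_y: int
    areas: list[int]

    def __post_init__(self) -> None:
        if any(a < 0 for a in self.areas):
            raise ValueError("green areas must be non-negative")


@dataclass
class ExperimentRecord:
    """One analysis-ready record: a measurement placed in the design."""

    time_from_start: float  # fractional days since first acquisition
    treatment: str
    treatment_code: int
    plate_type: str
    table_position: tuple[int, int]
    plate_id: str
    areas: list[int]


def parse_filename(name: str) -> tuple[datetime, tuple[int, int]]:
    """Extract (acquisition_time, camera (x, y)) from an image filename.

    The convention is ``<YYYYMMDD>T<HHMMSS>_x<int>_y<int>.png``.
    """
    m = _FILENAME_RE.match(name)
    if m is None:
        raise FilenameError(
            f"filename {name!r} does not match <YYYYMMDD>T<HHMMSS>_x<int>_y<int>.png")
    try:
        t = datetime.strptime(m["date"] + m["time"], "%Y%m%d%H%M%S")
    except ValueError as exc:
        raise FilenameError(f"invalid date/time in {name!r}: {exc}") from None
    return t, (int(m["x"]), int(m["y"]))


def format_filename(acquisition_time: datetime, camera_xy: tuple[int, int]) -> str:
    """Inverse of :func:`parse_filename` (zero-pads x/y to four digits)."""
    x, y = camera_xy
    return f"{acquisition_time:%Y%m%dT%H%M%S}_x{x:04d}_y{y:04d}.png"


def _rows_to_frame(rows: list[MeasurementRow]) -> pd.DataFrame:
    n_wells = {len(r.areas) for r in rows}
    if len(n_wells) > 1:
        raise ValueError(f"mixed plate formats in one sheet: area counts {sorted(n_wells)}")
    n = n_wells.pop() if n_wells else 0
    cols = ["filename", "date", "x", "y"] + [f"area_{i}" for i in range(1, n + 1)]
    data = [[r.filename, r.acquisition_time, r.camera_x, r.camera_y, *r.areas]
            for r in rows]
    return pd.DataFrame(data, columns=cols if rows else ["filename", "date", "x", "y"])


def export_table(rows: list[MeasurementRow], path) -> Path:
    """Write measurement rows as XLSX or CSV (by extension).

    Column order is exactly filename, date, x, y, area_1..area_n with wells
    column-wise, one row per image; re-importing yields identical values.
    """
    path = Path(path)
    frame = _rows_to_frame(rows)
    if path.suffix.lower() == ".xlsx":
        frame.to_excel(path, index=False)
    else:
        frame.to_csv(path, index=False)
    return path


def import_table(path) -> list[MeasurementRow]:
    """Read back a table written by :func:`export_table`."""
    path = Path(path)
    if path.suffix.lower() == ".xlsx":
        frame = pd.read_excel(path)
    else:
        frame = pd.read_csv(path, parse_dates=["date"])
    area_cols = [c for c in frame.columns if str(c).startswith("area_")]
    rows = []
    for _, r in frame.iterrows():
        rows.append(MeasurementRow(
            filename=str(r["filename"]),
            acquisition_time=pd.Timestamp(r["date"]).to_pydatetime(),
            camera_x=int(r["x"]), camera_y=int(r["y"]),
            areas=[int(r[c]) for c in area_cols]))
    return rows


def build_experiment(rows: list[MeasurementRow],
                     design: ExperimentDesign) -> list[ExperimentRecord]:
    """Join measurement rows with the design into one record per image.

    ``time_from_start`` is fractional days since the earliest acquisition in
    the set.  Plate identity is recovered from the camera (x, y) via the
    design's position map; an unmapped position is a design mismatch.
    Records preserve input cardinality and are ordered by acquisition time
    within each plate.
    """
    if not rows:
        return []
    t0 = min(r.acquisition_time for r in rows)
    records = []
    for r in sorted(rows, key=lambda r: (r.camera_x, r.camera_y, r.acquisition_time)):
        try:
            pid = design.plate_for_position((r.camera_x, r.camera_y))
        except KeyError as exc:
            raise KeyError(
                f"image {r.filename!r}: no plate in the design at position "
                f"({r.camera_x}, {r.camera_y})") from exc
        label, pos = design.plate_assignments[pid]
        records.append(ExperimentRecord(
            time_from_start=(r.acquisition_time - t0).total_seconds() / 86400.0,
            treatment=label,
            treatment_code=design.variants[label],
            plate_type=design.format_name,
            table_position=tuple(pos),
            plate_id=pid,
            areas=list(r.areas)))
    return records


def records_to_frame(records: list[ExperimentRecord]) -> pd.DataFrame:
    """Long-format DataFrame: one row per (record, well)."""
    out = []
    for rec in records:
        for w, a in enumerate(rec.areas, start=1):
            out.append(dict(time=rec.time_from_start, treatment=rec.treatment,
                            code=rec.treatment_code, plate_type=rec.plate_type,
                            plate_id=rec.plate_id, well=w, area=a))
    return pd.DataFrame(out)


def capacity_plan(format_name: str, platform_plates: int,
                  replicates_per_variant: int) -> tuple[int, int]:
    """Throughput arithmetic for a platform run.

    With one plant per well, ``total_plants = plates x wells_per_plate`` and
    the number of simultaneously testable variants is
    ``floor(plates / replicates)``.  E.g. 480 24-well plates at one replicate
    per variant carry 11,520 plants across 480 variants.
    """
    if platform_plates < 0:
        raise ValueError("platform_plates must be >= 0")
    if replicates_per_variant < 1:
        raise ValueError("replicates_per_variant must be >= 1")
    wells = standard_layout(format_name).wells_per_plate
    total_plants = platform_plates * wells
    n_variants = platform_plates // replicates_per_variant
    return total_plants, n_variants
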