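"""Plate geometry, well indexing and experiment-design bookkeeping.

Coordinate conventions used throughout the package:

* **Plate coordinates** are physical millimetres with the origin at the
  top-left corner of the plate rectangle, x to the right, y downwards.
* **Image coordinates** are 0-based pixels, ``(x, y) = (column, row)``,
  origin at the top-left of the raster.

Wells are numbered column-wise starting at the top-left well: index 1 is
row 1 / column 1, index 2 is row 2 / column 1, and so on down each column,
with columns taken left to right.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import yaml

__all__ = [
    "PlateLayout",
    "WellIndex",
    "ExperimentDesign",
    "well_index",
    "well_from_index",
    "standard_layout",
    "layout_from_config",
]


# Physical footprints of common commercial multi-well plates (ANSI/SLAS
# microplate footprint for the plate rectangle; well pitch and diameter from
# typical vendor drawings).  All values in millimetres, overridable via
# layout_from_config.
_STANDARD_FORMATS: dict[str, dict] = {
    "6-well": dict(n_rows=2, n_cols=3, plate_width=127.76, plate_height=85.48,
                   pitch=39.12, well_radius=17.5),
    "12-well": dict(n_rows=3, n_cols=4, plate_width=127.76, plate_height=85.48,
                    pitch=26.01, well_radius=11.0),
    "24-well": dict(n_rows=4, n_cols=6, plate_width=127.76, plate_height=85.48,
                    pitch=19.3, well_radius=8.0),
}


@dataclass(frozen=True)
class PlateLayout:
    """Geometry of a multi-well plate.

    Well centres form a regular grid centred on the plate rectangle with
    spacing ``pitch`` mm; each well is a disc of radius ``well_radius`` mm.
    """

    format_name: str
    n_rows: int
    n_cols: int
    plate_width: float
    plate_height: float
    pitch: float
    well_radius: float

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.well_radius <= 0 or self.pitch <= 0:
            raise ValueError("pitch and well_radius must be positive")
        if 2 * self.well_radius > self.pitch:
            raise ValueError("well discs overlap: 2*radius exceeds pitch")
        # all well discs must lie inside the plate rectangle
        x0, y0 = self.well_center(1, 1)
        x1, y1 = self.well_center(self.n_rows, self.n_cols)
        r = self.well_radius
        if x0 - r < 0 or y0 - r < 0 or x1 + r > self.plate_width or y1 + r > self.plate_height:
            raise ValueError("well discs extend outside the plate rectangle")

    @property
    def wells_per_plate(self) -> int:
        return self.n_rows * self.n_cols

    def well_center(self, row: int, col: int) -> tuple[float, float]:
        """Centre of the well at (row, col), 1-based, in plate mm (x, y)."""
        if not (1 <= row <= self.n_rows and 1 <= col <= self.n_cols):
            raise IndexError(f"well ({row}, {col}) outside {self.n_rows}x{self.n_cols} grid")
        cx = self.plate_width / 2 + (col - 1 - (self.n_cols - 1) / 2) * self.pitch
        cy = self.plate_height / 2 + (row - 1 - (self.n_rows - 1) / 2) * self.pitch
        return (cx, cy)

    def well_centers(self) -> np.ndarray:
        """All well centres in column-wise linear-index order, shape (n, 2)."""
        pts = []
        for col in range(1, self.n_cols + 1):
            for row in range(1, self.n_rows + 1):
                pts.append(self.well_center(row, col))
        return np.asarray(pts, dtype=float)


def mark_template(layout: PlateLayout, margin: float = 6.0) -> np.ndarray:
    """Plate-coordinate positions (mm) of the four blue tray fiducials.

    Three marks sit just outside the plate corners (top-left, top-right,
    bottom-right); the fourth sits at mid-height on the left edge.  The
    deliberately *asymmetric* pattern means no rotation or reflection of the
    plate maps the mark set onto itself, so a similarity registration
    estimated from mark correspondences is orientation-unambiguous (a
    rectangle of marks would make a 180-degree-rotated registration
    geometrically perfect and undetectable).
    Order: top-left, top-right, bottom-right, left-middle.
    """
    w, h = layout.plate_width, layout.plate_height
    m = margin
    return np.array([
        (-m, -m),
        (w + m, -m),
        (w + m, h + m),
        (-m, h / 2),
    ], dtype=float)


@dataclass(frozen=True)
class WellIndex:
    """A well's 1-based position, both linear (column-wise) and as (row, col)."""

    linear_index: int
    row: int
    col: int


def well_index(row: int, col: int, layout: PlateLayout) -> WellIndex:
    """Column-wise 1-based linear index of the well at (row, col).

    ``linear_index = (col - 1) * n_rows + row``: wells are numbered down each
    column, columns left to right, starting at the top-left well.
    """
    if not (1 <= row <= layout.n_rows):
        raise IndexError(f"row {row} outside 1..{layout.n_rows}")
    if not (1 <= col <= layout.n_cols):
        raise IndexError(f"col {col} outside 1..{layout.n_cols}")
    return WellIndex(linear_index=(col - 1) * layout.n_rows + row, row=row, col=col)


def well_from_index(linear_index: int, layout: PlateLayout) -> WellIndex:
    """Inverse of :func:`well_index`: recover (row, col) from the linear index."""
    n = layout.wells_per_plate
    if not (1 <= linear_index <= n):
        raise IndexError(f"linear index {linear_index} outside 1..{n}")
    col = (linear_index - 1) // layout.n_rows + 1
    row = (linear_index - 1) % layout.n_rows + 1
    return WellIndex(linear_index=linear_index, row=row, col=col)


def standard_layout(format_name: str) -> PlateLayout:
    """Built-in layout for one of the supported formats (6-, 12-, 24-well)."""
    try:
        params = _STANDARD_FORMATS[format_name]
    except KeyError:
        raise ValueError(
            f"unknown plate format {format_name!r}; supported: {sorted(_STANDARD_FORMATS)}"
        ) from None
    return PlateLayout(format_name=format_name, **params)


def layout_from_config(path) -> PlateLayout:
    """Load a plate layout from a YAML file; omitted keys fall back to the
    named standard format."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    name = cfg.get("format_name", "24-well")
    base = dict(_STANDARD_FORMATS.get(name, _STANDARD_FORMATS["24-well"]))
    base.update({k: cfg[k] for k in
                 ("n_rows", "n_cols", "plate_width", "plate_height", "pitch", "well_radius")
                 if k in cfg})
    return PlateLayout(format_name=name, **base)


@dataclass
class ExperimentDesign:
    """Assignment of plates to treatment variants and platform positions.

    ``variants`` maps treatment label -> numeric code (codes unique per
    label); ``plate_assignments`` maps plate-id -> (treatment label,
    table position (x, y)).  One plant per well is assumed, as on the
    source platform.
    """

    format_name: str
    variants: dict[str, int]
    replicates_per_variant: int
    plate_assignments: dict[str, tuple[str, tuple[int, int]]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.replicates_per_variant < 1:
            raise ValueError("replicates_per_variant must be >= 1")
        codes = list(self.variants.values())
        if len(set(codes)) != len(codes):
            raise ValueError("treatment numeric codes must be unique")
        for pid, (label, _pos) in self.plate_assignments.items():
            if label not in self.variants:
                raise ValueError(f"plate {pid!r} assigned to unknown variant {label!r}")

    @property
    def layout(self) -> PlateLayout:
        return standard_layout(self.format_name)

    @property
    def plants_per_variant(self) -> int:
        """Plants per variant: replicates x wells per plate (one plant/well)."""
        return self.replicates_per_variant * self.layout.wells_per_plate

    def plate_for_position(self, xy: tuple[int, int]) -> str:
        """Recover the plate-id imaged at camera position (x, y)."""
        for pid, (_label, pos) in self.plate_assignments.items():
            if tuple(pos) == tuple(xy):
                return pid
        raise KeyError(f"no plate assigned to camera position {xy}")

    @classmethod
    def simple(cls, format_name: str, treatments: list[str],
               replicates_per_variant: int) -> "ExperimentDesign":
        """Design with auto-assigned codes (sorted label order) and plates laid
        out on a grid of camera positions, one column of replicates per variant."""
        variants = {t: i + 1 for i, t in enumerate(sorted(treatments))}
        assignments = {}
        for vi, t in enumerate(sorted(treatments)):
            for r in range(replicates_per_variant):
                pid = f"{t}_r{r + 1}"
                assignments[pid] = (t, (vi * 200, r * 150))
        return cls(format_name=format_name, variants=variants,
                   replicates_per_variant=replicates_per_variant,
                   plate_assignments=assignments)


def design_from_config(path) -> ExperimentDesign:
    """Load an experiment design from YAML.

    Schema::

        format_name: 24-well
        replicates_per_variant: 3
        variants: {Control: 1, NaCl150: 2}   # or a list of labels
        plates:
          plate01: {variant: Control, position: [0, 0]}
    """
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    variants = cfg.get("variants")
    if isinstance(variants, list):
        variants = {t: i + 1 for i, t in enumerate(sorted(variants))}
    assignments = {
        pid: (p["variant"], tuple(p["position"]))
        for pid, p in (cfg.get("plates") or {}).items()
    }
    return ExperimentDesign(
        format_name=cfg.get("format_name", "24-well"),
        variants=variants or {},
        replicates_per_variant=int(cfg.get("replicates_per_variant", 1)),
        plate_assignments=assignments,
    )
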