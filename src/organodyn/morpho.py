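"""Morphometric quantifications of delineated progenitor-cell geometry.

Downstream of manual or automatic delineation these helpers compute apical
footprint areas from tight-junction (ZO1) perimeter polygons, nuclear
positions as a percentage of apicobasal tissue thickness, apical-process
volume:surface ratios, fold-reduction summaries, and tidy per-group
descriptive statistics. Inferential statistics are deliberately left to
downstream tools; the outputs here are plain tables.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "CellOutline",
    "NuclearPositionRecord",
    "polygon_area",
    "nuclear_position",
    "volume_surface_ratio",
    "fold_reduction",
    "group_summary",
]


@dataclass(frozen=True)
class CellOutline:
    """A delineated apical cell perimeter: simple polygon in microns."""

    cell_id: str
    vertices: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if len(self.vertices) < 3:
            raise ValueError("an outline needs at least 3 vertices")


@dataclass(frozen=True)
class NuclearPositionRecord:
    apical_distance_um: float
    total_thickness_um: float
    percent: float
    clamped: bool = False


def polygon_area(outline: CellOutline | Sequence[tuple[float, float]]) -> float:
    """Shoelace area of a simple polygon in square microns.

    Orientation-independent (absolute value). Self-intersecting outlines are
    rejected rather than silently mismeasured.
    """
    verts = outline.vertices if isinstance(outline, CellOutline) else tuple(outline)
    if len(verts) < 3:
        raise ValueError("a polygon needs at least 3 vertices")
    if not _ShapelyPolygon(verts).is_valid:
        raise ValueError("polygon is self-intersecting or degenerate")
    xy = np.asarray(verts, dtype=float)
    x, y = xy[:, 0], xy[:, 1]
    area = 0.5 * np.abs(np.dot(x, np.roll(y, -1)) - np.dot(np.roll(x, -1), y))
    return float(area)


def nuclear_position(
    apical_distance_um: float, thickness_measurements_um: Sequence[float]
) -> NuclearPositionRecord:
    """Nuclear distance from the apical surface as % of apicobasal thickness.

    The denominator is the mean of three independent thickness measurements
    of the neuroepithelial tissue. Distances beyond the mean thickness (from
    oblique sections) are clamped to 100% with a warning.
    """
    thick = np.asarray(thickness_measurements_um, dtype=float)
    if np.any(thick <= 0):
        raise ValueError("thickness measurements must be positive")
    if apical_distance_um < 0:
        raise ValueError("apical distance must be non-negative")
    mean_thickness = float(np.mean(thick))
    percent = 100.0 * apical_distance_um / mean_thickness
    clamped = False
    if percent > 100.0:
        warnings.warn(
            f"apical distance {apical_distance_um} exceeds mean thickness "
            f"{mean_thickness:.3g}; clamping to 100% (oblique section?)",
            stacklevel=2,
        )
        percent = 100.0
        clamped = True
    return NuclearPositionRecord(apical_distance_um, mean_thickness, percent, clamped)


def volume_surface_ratio(volume_um3: float, surface_area_um2: float) -> float:
    """Volume normalized to surface area (microns); thickness proxy for apical processes."""
    if volume_um3 <= 0 or surface_area_um2 <= 0:
        raise ValueError("volume and surface area must be positive")
    return volume_um3 / surface_area_um2


def fold_reduction(mean_early: float, mean_late: float) -> tuple[float, str]:
    """Ratio of an early-timepoint mean to a late one.

    Returns the ratio rounded to one decimal and a nearest-integer
    ``"N-fold"`` label (e.g. 13.82/1.92 -> ``(7.2, "7-fold")``).
    """
    if mean_early <= 0 or mean_late <= 0:
        raise ValueError("means must be positive")
    ratio = mean_early / mean_late
    label = f"{round(ratio):d}-fold"
    return round(ratio, 1), label


def group_summary(values_by_group: Mapping[str, Iterable[float]]) -> pd.DataFrame:
    """Descriptive statistics per group: mean, SD, n, median, min, max.

    Empty groups are excluded with a warning; singleton groups report SD 0
    with ``sd_defined = False``. No hypothesis testing is performed.
    """
    rows = []
    for group, values in values_by_group.items():
        arr = np.asarray(list(values), dtype=float)
        if arr.size == 0:
            warnings.warn(f"group {group!r} is empty; excluded", stacklevel=2)
            continue
        sd_defined = arr.size > 1
        rows.append(
            {
                "group": group,
                "n": int(arr.size),
                "mean": float(np.mean(arr)),
                "sd": float(np.std(arr, ddof=1)) if sd_defined else 0.0,
                "sd_defined": sd_defined,
                "median": float(np.median(arr)),
                "min": float(np.min(arr)),
                "max": float(np.max(arr)),
            }
        )
    return pd.DataFrame(
        rows, columns=["group", "n", "mean", "sd", "sd_defined", "median", "min", "max"]
    )


def outlines_from_frame(df: pd.DataFrame) -> list[CellOutline]:
    """Read outlines from a long table (cell_id, vertex_index, x_um, y_um)."""
    outlines = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("vertex_index")
        verts = tuple(zip(grp["x_um"].astype(float), grp["y_um"].astype(float)))
        outlines.append(CellOutline(str(cid), verts))
    return outlines
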