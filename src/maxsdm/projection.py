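"""Projection onto raster stacks, GCM ensembles, five-class suitability
classification and spherical area / range-change accounting."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import transform_features
from .model import MaxentModel, predict_cloglog
from .raster import RasterGrid, RasterStack

__all__ = [
    "project_map",
    "ensemble_mean",
    "ClassifiedMap",
    "classify_suitability",
    "class_areas",
    "change_table",
    "CLASS_NAMES",
    "EARTH_RADIUS_KM",
]

# authalic (equal-area) sphere radius
EARTH_RADIUS_KM = 6371.0088

CLASS_NAMES = {0: "unsuitable", 1: "low", 2: "moderate", 3: "optimum", 4: "high"}


def project_map(model: MaxentModel, stack: RasterStack) -> RasterGrid:
    """Cloglog suitability map over the stack's valid cells.

    Transforms each valid cell's predictor values with the model's stored
    bounds/knots (clamping novel climates) and applies the cloglog output;
    nodata propagates.
    """
    missing = [v for v in model.defs.variables if v not in stack]
    if missing:
        raise KeyError(f"stack missing model variable(s): {missing}")
    ref = stack.reference
    matrix, flat_idx = stack.to_matrix(model.defs.variables)
    out = np.full(ref.nrows * ref.ncols, ref.nodata)
    if matrix.shape[0]:
        df = pd.DataFrame(matrix, columns=model.defs.variables)
        out[flat_idx] = predict_cloglog(model, transform_features(df, model.defs))
    return ref.with_values(out.reshape(ref.nrows, ref.ncols))


def ensemble_mean(maps: list[RasterGrid]) -> RasterGrid:
    """Cellwise unweighted mean across aligned maps (e.g. one per GCM).

    A cell is nodata in the output if it is nodata in any input.
    """
    if not maps:
        raise ValueError("ensemble_mean needs at least one map")
    ref = maps[0]
    for g in maps[1:]:
        if not g.same_geometry(ref):
            raise ValueError("ensemble maps are not aligned")
    valid = np.ones((ref.nrows, ref.ncols), dtype=bool)
    for g in maps:
        valid &= g.valid_mask
    total = np.zeros((ref.nrows, ref.ncols))
    for g in maps:
        total += np.where(valid, g.values, 0.0)
    mean = np.where(valid, total / len(maps), ref.nodata)
    return ref.with_values(mean)


@dataclass
class ClassifiedMap:
    """Five-class suitability map with its break vector.

    Codes: 0 unsuitable, 1 low, 2 moderate, 3 optimum, 4 high; breaks are
    (t, 2t, 3t, 4t) from the maxSSS threshold t.
    """

    grid: RasterGrid  # integer class codes, nodata preserved
    breaks: tuple[float, float, float, float]
    threshold: float


def classify_suitability(
    suitability: RasterGrid,
    t: float | None = None,
    breaks: tuple[float, float, float, float] | None = None,
) -> ClassifiedMap:
    """Classify a cloglog map into five suitability classes.

    With a threshold ``t`` (the maxSSS cut, required to satisfy
    0 < t < 0.25) the breaks are (t, 2t, 3t, 4t): class 0 below t, then
    one class per band, class 4 at or above 4t.  Explicit ``breaks`` may
    be supplied instead.
    """
    if breaks is None:
        if t is None:
            raise ValueError("either t or explicit breaks are required")
        if not 0 < t < 0.25:
            raise ValueError(f"t must lie in (0, 0.25) so that 4t < 1; got {t}")
        breaks = (t, 2 * t, 3 * t, 4 * t)
    else:
        t = breaks[0]
    b = np.asarray(breaks, dtype=float)
    if not (np.all(np.diff(b) > 0) and 0 < b[0] and b[-1] < 1):
        raise ValueError(f"breaks must be strictly increasing within (0, 1): {breaks}")
    valid = suitability.valid_mask
    codes = np.digitize(suitability.values, b, right=False).astype(float)
    codes = np.where(valid, codes, suitability.nodata)
    return ClassifiedMap(
        grid=suitability.with_values(codes),
        breaks=tuple(float(x) for x in b),
        threshold=float(t),
    )


def _row_cell_area_km2(grid: RasterGrid) -> np.ndarray:
    """Area of one cell in each lattice row on the authalic sphere.

    A cell spanning latitudes [phi1, phi2] and dlambda of longitude has
    area R^2 * dlambda_rad * (sin phi2 - sin phi1).
    """
    d = math.radians(grid.cellsize)
    rows = np.arange(grid.nrows)
    lat_top = grid.yll + (grid.nrows - rows) * grid.cellsize
    lat_bot = lat_top - grid.cellsize
    return (
        EARTH_RADIUS_KM**2
        * d
        * (np.sin(np.radians(lat_top)) - np.sin(np.radians(lat_bot)))
    )


def class_areas(classified: ClassifiedMap, scenario: str = "present") -> pd.Series:
    """Per-class area in km2 (plus total) for one scenario.

    Cell areas follow the spherical formula with the authalic radius;
    nodata cells are excluded from every class and from the total.
    """
    grid = classified.grid
    row_area = _row_cell_area_km2(grid)
    valid = grid.valid_mask
    areas = {}
    for code, name in CLASS_NAMES.items():
        mask = valid & (grid.values == code)
        areas[name] = float((mask * row_area[:, None]).sum())
    areas["total"] = float((valid * row_area[:, None]).sum())
    return pd.Series(areas, name=scenario)


def change_table(
    present: pd.Series, future: pd.Series, denominator: str = "present"
) -> pd.Series:
    """Percent change in class area between two scenarios.

    ``denominator="present"``: 100 * (A_f - A_p) / A_p (sign positive =
    expansion); ``"future"`` divides by A_f instead.  A class going from
    zero area to nonzero yields +/-inf rather than a number.
    """
    if denominator not in ("present", "future"):
        raise ValueError("denominator must be 'present' or 'future'")
    out = {}
    for name in CLASS_NAMES.values():
        a_p, a_f = float(present[name]), float(future[name])
        denom = a_p if denominator == "present" else a_f
        diff = a_f - a_p
        if denom == 0:
            out[name] = 0.0 if diff == 0 else math.copysign(math.inf, diff)
        else:
            out[name] = 100.0 * diff / denom
    s = pd.Series(out, name=f"change_vs_{denominator}")
    s.attrs["denominator"] = denominator
    return s
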