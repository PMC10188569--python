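"""Occurrence records and point-sample extraction from raster stacks."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .raster import RasterGrid, RasterStack

__all__ = [
    "OccurrenceSet",
    "SampleMatrix",
    "read_occurrences_csv",
    "extract_samples",
    "background_samples",
]

log = logging.getLogger("maxsdm")


@dataclass
class OccurrenceSet:
    """Presence records as (longitude, latitude) pairs with a species label."""

    records: list[tuple[float, float]]
    species: str = "species"

    def __len__(self) -> int:
        return len(self.records)

    def dedupe_per_cell(self, grid: RasterGrid) -> "OccurrenceSet":
        """Keep at most one record per grid cell (first wins). Idempotent."""
        seen: set[tuple[int, int]] = set()
        kept: list[tuple[float, float]] = []
        for lon, lat in self.records:
            idx = grid.cell_index(lon, lat)
            if idx not in seen:
                seen.add(idx)
                kept.append((lon, lat))
        return OccurrenceSet(kept, self.species)


@dataclass
class SampleMatrix:
    """Point × variable values extracted from a stack.

    ``provenance`` distinguishes presence samples from background samples;
    the data frame never contains nodata values.
    """

    data: pd.DataFrame
    provenance: str = "presence"  # "presence" | "background"
    cell_indices: np.ndarray | None = field(default=None, repr=False)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def __len__(self) -> int:
        return len(self.data)


def read_occurrences_csv(
    path: str | Path,
    grid: RasterGrid | None = None,
    dedupe_per_cell: bool = False,
    species_col: str = "species",
    lon_col: str = "longitude",
    lat_col: str = "latitude",
) -> OccurrenceSet:
    """Read occurrences from a CSV with species/longitude/latitude columns.

    Points outside the grid bounding box are dropped (with a logged count);
    with ``dedupe_per_cell`` at most one record per grid cell is kept.
    """
    df = pd.read_csv(path)
    for col in (species_col, lon_col, lat_col):
        if col not in df.columns:
            raise ValueError(f"occurrence CSV missing required column {col!r}")
    for col in (lon_col, lat_col):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # 1-based + header line
            raise ValueError(
                f"non-numeric coordinate in column {col!r} at line {line}"
            )
        df[col] = coerced
    df = df.dropna(subset=[lon_col, lat_col])
    species = str(df[species_col].iloc[0]) if len(df) else "species"
    records = list(zip(df[lon_col].astype(float), df[lat_col].astype(float)))
    if grid is not None:
        inside = [(x, y) for x, y in records if grid.contains(x, y)]
        n_dropped = len(records) - len(inside)
        if n_dropped:
            log.warning("%d occurrence(s) outside grid bounds dropped", n_dropped)
        records = inside
    occ = OccurrenceSet(records, species)
    if dedupe_per_cell:
        if grid is None:
            raise ValueError("dedupe_per_cell requires a reference grid")
        before = len(occ)
        occ = occ.dedupe_per_cell(grid)
        if len(occ) != before:
            log.info("cell-deduplication: %d -> %d records", before, len(occ))
    return occ


def extract_samples(stack: RasterStack, points: OccurrenceSet) -> SampleMatrix:
    """Extract per-point values from every stack layer.

    Each point takes the value of the cell containing it (half-open cell
    membership, lower-left origin).  Points falling on a nodata cell in any
    layer are dropped and counted; an empty result raises.
    """
    ref = stack.reference
    names = stack.names
    rows: list[list[float]] = []
    cells: list[int] = []
    n_nodata = 0
    for lon, lat in points.records:
        r, c = ref.cell_index(lon, lat)
        vals = [stack[n].values[r, c] for n in names]
        if any(v == stack[n].nodata for v, n in zip(vals, names)):
            n_nodata += 1
            continue
        rows.append(vals)
        cells.append(r * ref.ncols + c)
    if n_nodata:
        log.warning("%d point(s) over nodata cells dropped", n_nodata)
    if not rows:
        raise ValueError("no valid samples: every point fell on nodata or none given")
    df = pd.DataFrame(rows, columns=names)
    return SampleMatrix(df, provenance="presence", cell_indices=np.array(cells))


def background_samples(
    stack: RasterStack,
    n_background: int = 10_000,
    seed: int | None = None,
    names: list[str] | None = None,
) -> SampleMatrix:
    """Sample up to ``n_background`` valid cells uniformly without replacement.

    All valid cells are used when fewer than ``n_background`` exist.  The
    draw is deterministic under ``seed``.
    """
    names = names or stack.names
    matrix, flat_idx = stack.to_matrix(names)
    if matrix.shape[0] == 0:
        raise ValueError("no valid cells available for background sampling")
    if matrix.shape[0] > n_background:
        rng = np.random.default_rng(seed)
        pick = rng.choice(matrix.shape[0], size=n_background, replace=False)
        pick.sort()
        matrix, flat_idx = matrix[pick], flat_idx[pick]
    df = pd.DataFrame(matrix, columns=names)
    return SampleMatrix(df, provenance="background", cell_indices=flat_idx)
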