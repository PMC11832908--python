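"""Fixed-resolution square-grid assignment and per-source occupancy.

Georeferenced records are projected to a metric plane and binned into
half-open square cells (default 10 x 10 km). Occupancy — the number of cells
holding at least one record of a source — is the standard atlas-style measure
of a recording scheme's spatial coverage, and comparing it across sources
shows e.g. how spatially restricted structured sampling is relative to
opportunistic citizen science.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .projection import geodetic_to_projected, in_validity_domain
from .records import OccurrenceRecord, Source

__all__ = ["GridSpec", "OccupancyResult", "assign_cell", "assign_cells", "occupancy_by_source"]

CellId = tuple[int, int]


@dataclass(frozen=True)
class GridSpec:
    """A square grid on a metric planar frame.

    Cells are half-open squares ``[x0 + i*s, x0 + (i+1)*s) x [y0 + j*s, ...)``
    so every projected point maps to exactly one cell: a point on a shared
    edge belongs to the cell whose lower/left boundary it sits on. ``origin``
    ``None`` means "derive from data" (the minimum projected coordinate,
    floored to a cell multiple, so ids are stable under record addition
    within the same extent). ``region_mask``, when given, fixes the set of
    valid region cells (the denominator of occupancy percentages).
    """

    cell_size: float = 10_000.0
    projection: str = "utm32n"
    origin: tuple[float, float] | None = None
    region_mask: frozenset[CellId] | None = None

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError("cell_size must be positive")

    def with_origin_from(self, x: np.ndarray, y: np.ndarray) -> "GridSpec":
        if self.origin is not None or x.size == 0:
            return self
        s = self.cell_size
        origin = (float(np.floor(x.min() / s) * s), float(np.floor(y.min() / s) * s))
        return GridSpec(self.cell_size, self.projection, origin, self.region_mask)

    def cell_of(self, x: float, y: float) -> CellId:
        if self.origin is None:
            raise ValueError("grid origin not set")
        x0, y0 = self.origin
        return (
            int(np.floor((x - x0) / self.cell_size)),
            int(np.floor((y - y0) / self.cell_size)),
        )

    @staticmethod
    def mask_from_file(path: str | Path) -> frozenset[CellId]:
        """Read a region mask: JSON list of [col, row] pairs."""
        pairs = json.loads(Path(path).read_text())
        return frozenset((int(c), int(r)) for c, r in pairs)


def assign_cell(record: OccurrenceRecord, grid: GridSpec) -> CellId | None:
    """Cell of a single record, or ``None`` if it has no coordinates.

    Raises ``ValueError`` for coordinates outside the projection's validity
    domain; the batch API counts those instead.
    """
    if not record.georeferenced:
        return None
    ok = in_validity_domain([record.longitude], [record.latitude], grid.projection)
    if not bool(ok[0]):
        raise ValueError(
            f"{record.species}: coordinates ({record.latitude}, {record.longitude}) "
            f"outside validity domain of {grid.projection!r}"
        )
    x, y = geodetic_to_projected([record.longitude], [record.latitude], grid.projection)
    return grid.with_origin_from(x, y).cell_of(float(x[0]), float(y[0]))


def assign_cells(
    records: Sequence[OccurrenceRecord], grid: GridSpec
) -> tuple[list[CellId | None], GridSpec, int]:
    """Vectorised cell assignment for a record batch.

    Returns per-record cell ids (``None`` for records without coordinates or
    outside the projection domain), the grid with its origin resolved, and
    the count of out-of-domain records.
    """
    geo_idx = [i for i, r in enumerate(records) if r.georeferenced]
    lon = np.array([records[i].longitude for i in geo_idx], dtype=float)
    lat = np.array([records[i].latitude for i in geo_idx], dtype=float)
    cells: list[CellId | None] = [None] * len(records)
    if not geo_idx:
        return cells, grid, 0
    ok = in_validity_domain(lon, lat, grid.projection)
    x, y = geodetic_to_projected(lon[ok], lat[ok], grid.projection)
    grid = grid.with_origin_from(x, y)
    x0, y0 = grid.origin if grid.origin is not None else (0.0, 0.0)
    cols = np.floor((x - x0) / grid.cell_size).astype(int)
    rows = np.floor((y - y0) / grid.cell_size).astype(int)
    for (i, c, r) in zip(np.asarray(geo_idx)[ok], cols, rows):
        cells[int(i)] = (int(c), int(r))
    return cells, grid, int((~ok).sum())


@dataclass
class OccupancyResult:
    """Per-source occupancy plus the full per-cell count table.

    ``occupancy`` maps each source value to (occupied cells, total region
    cells, percentage). ``cells`` has one row per occupied (or masked) cell
    with per-source counts and the total. ``n_not_georeferenced`` and
    ``n_out_of_domain`` account for every record not in the table.
    """

    occupancy: dict[str, tuple[int, int, float]]
    cells: pd.DataFrame
    total_region_cells: int
    n_not_georeferenced: int
    n_out_of_domain: int
    n_outside_mask: int = 0
    grid: GridSpec | None = None

    def as_dict(self) -> dict:
        return {
            "occupancy": {
                s: {"occupied": occ, "total_cells": tot, "pct": pct}
                for s, (occ, tot, pct) in self.occupancy.items()
            },
            "total_region_cells": self.total_region_cells,
            "n_not_georeferenced": self.n_not_georeferenced,
            "n_out_of_domain": self.n_out_of_domain,
            "n_outside_mask": self.n_outside_mask,
        }


def occupancy_by_source(
    records: Sequence[OccurrenceRecord], grid: GridSpec
) -> OccupancyResult:
    """Grid the records and measure each source's spatial coverage.

    A cell is occupied for a source if at least one in-domain record of that
    source falls in it. The region denominator is ``grid.region_mask`` when
    supplied; otherwise the union of cells occupied by any source. Records in
    cells outside an explicit mask are counted separately and excluded from
    the occupancy numerators.
    """
    import warnings

    cells, grid, n_bad = assign_cells(records, grid)
    rows = [
        {"col": c[0], "row": c[1], "source": r.source.value}
        for r, c in zip(records, cells)
        if c is not None
    ]
    n_no_geo = sum(1 for r in records if not r.georeferenced)
    if not rows:
        warnings.warn("no georeferenced records: occupancy table is empty", stacklevel=2)
        empty = pd.DataFrame(
            columns=["col", "row", *(s.value for s in Source), "total"]
        )
        total = len(grid.region_mask) if grid.region_mask else 0
        return OccupancyResult(
            occupancy={s.value: (0, total, 0.0) for s in Source},
            cells=empty,
            total_region_cells=total,
            n_not_georeferenced=n_no_geo,
            n_out_of_domain=n_bad,
            grid=grid,
        )

    df = pd.DataFrame(rows)
    n_outside_mask = 0
    if grid.region_mask is not None:
        inside = df.apply(lambda r: (r["col"], r["row"]) in grid.region_mask, axis=1)
        n_outside_mask = int((~inside).sum())
        df = df[inside]
    table = (
        df.pivot_table(index=["col", "row"], columns="source", aggfunc="size", fill_value=0)
        .reindex(columns=[s.value for s in Source], fill_value=0)
        .reset_index()
    )
    table.columns.name = None
    table["total"] = table[[s.value for s in Source]].sum(axis=1)

    if grid.region_mask is not None:
        total_cells = len(grid.region_mask)
    else:
        total_cells = len(table)
    occupancy = {}
    for s in Source:
        occ = int((table[s.value] > 0).sum())
        pct = 100.0 * occ / total_cells if total_cells else 0.0
        occupancy[s.value] = (occ, total_cells, pct)
    return OccupancyResult(
        occupancy=occupancy,
        cells=table,
        total_region_cells=total_cells,
        n_not_georeferenced=n_no_geo,
        n_out_of_domain=n_bad,
        n_outside_mask=n_outside_mask,
        grid=grid,
    )
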