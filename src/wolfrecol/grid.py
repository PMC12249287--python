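"""Occupancy grid: build cells, assign records, classify Permanent/Sporadic/Absent.

The distribution analysis rasterizes verified occurrences onto a square grid
(default 10 x 10 km) and classifies each cell per multi-year period:

* a *qualifying year* is a year with >= 1 C1 or >= 2 C2 occurrences in the cell;
* **Permanent**: qualifying years in at least half of the period
  (``ceil(length/2)``, i.e. 3 of 5), or a reproduction event in the cell
  within the last three calendar years of the period;
* **Sporadic**: some C1/C2 presence but not Permanent;
* **Absent**: no C1/C2 record at all.

Cells are half-open ``[min, min+size)`` intervals on both axes so every point
maps to exactly one cell.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from shapely.geometry import box, mapping

from .records import ReproductionEvent

logger = logging.getLogger(__name__)

STATUS_ORDER = {"Absent": 0, "Sporadic": 1, "Permanent": 2}


@dataclass(frozen=True)
class Period:
    """An inclusive range of calendar years (e.g. 2015-2019)."""

    label: str
    start_year: int
    end_year: int

    def __post_init__(self):
        if self.end_year < self.start_year:
            raise ValueError("end_year before start_year")

    @property
    def length_years(self) -> int:
        return self.end_year - self.start_year + 1

    @property
    def years(self) -> range:
        return range(self.start_year, self.end_year + 1)


#: the study's two equal five-year intervals
DEFAULT_PERIODS = (Period("2015-2019", 2015, 2019), Period("2020-2024", 2020, 2024))


@dataclass
class CellPeriodStatus:
    cell_id: str
    period: str
    status: str  # Permanent | Sporadic | Absent
    qualifying_years: int
    presence_years: int
    reproduction_recent: bool


def build_grid(
    extent: tuple[float, float, float, float],
    cell_size: float = 10_000.0,
    origin: str = "snap",
) -> pd.DataFrame:
    """Tile a planar extent with square cells.

    Parameters
    ----------
    extent
        ``(min_x, min_y, max_x, max_y)`` in metres of a projected CRS.
    cell_size
        cell edge in metres (default 10 km).
    origin
        ``"snap"`` aligns the grid's lower-left corner to the cell-size
        lattice (so cells can line up with official national grids);
        ``"extent"`` starts at the extent's lower-left corner exactly.

    Returns a DataFrame with columns cell_id, row, col, min_x, min_y, size.
    """
    min_x, min_y, max_x, max_y = map(float, extent)
    if cell_size <= 0:
        raise ValueError("cell_size must be positive")
    if not (max_x > min_x and max_y > min_y):
        raise ValueError("extent must have positive width and height")
    if origin == "snap":
        x0 = math.floor(min_x / cell_size) * cell_size
        y0 = math.floor(min_y / cell_size) * cell_size
    elif origin == "extent":
        x0, y0 = min_x, min_y
    else:
        raise ValueError(f"unknown origin mode {origin!r}")
    n_cols = math.ceil((max_x - x0) / cell_size)
    n_rows = math.ceil((max_y - y0) / cell_size)
    rows, cols = np.mgrid[0:n_rows, 0:n_cols]
    rows, cols = rows.ravel(), cols.ravel()
    return pd.DataFrame(
        {
            "cell_id": [f"r{r}c{c}" for r, c in zip(rows, cols)],
            "row": rows,
            "col": cols,
            "min_x": x0 + cols * cell_size,
            "min_y": y0 + rows * cell_size,
            "size": cell_size,
        }
    )


def assign_cells(grid: pd.DataFrame, x, y) -> pd.Series:
    """Map point coordinates to cell ids (half-open cells; NaN if outside)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x0 = float(grid["min_x"].min())
    y0 = float(grid["min_y"].min())
    size = float(grid["size"].iloc[0])
    col = np.floor((x - x0) / size).astype(int)
    row = np.floor((y - y0) / size).astype(int)
    # enforce exact half-open membership at cell edges: division can round a
    # point sitting one ulp below an edge into the next cell
    col -= x < x0 + col * size
    col += x >= x0 + (col + 1) * size
    row -= y < y0 + row * size
    row += y >= y0 + (row + 1) * size
    n_cols = int(grid["col"].max()) + 1
    n_rows = int(grid["row"].max()) + 1
    inside = (col >= 0) & (col < n_cols) & (row >= 0) & (row < n_rows)
    ids = np.array([f"r{r}c{c}" for r, c in zip(row, col)], dtype=object)
    ids[~inside] = None
    return pd.Series(ids, name="cell_id")


def classify_cell(
    records_in_cell: pd.DataFrame,
    period: Period,
    reproduction_events: list[ReproductionEvent] | None = None,
    cell_id: str = "",
) -> CellPeriodStatus:
    """Classify one cell for one period from its SCALP-filtered records.

    ``records_in_cell`` must contain only C1/C2 records dated inside the
    period (callers pre-slice; out-of-period rows raise). Reproduction events
    are matched by the caller to this cell; only their years matter here.
    """
    repro_years = [e.year for e in (reproduction_events or [])]
    if len(records_in_cell):
        years = pd.to_datetime(records_in_cell["date"]).dt.year
        if ((years < period.start_year) | (years > period.end_year)).any():
            raise ValueError("records outside period; pre-slice before classify_cell")
        scalp = records_in_cell["scalp"]
        if (scalp == "C3").any():
            raise ValueError("C3 records must be removed before classification")
        per_year = pd.crosstab(years, scalp)
        c1 = per_year.get("C1", pd.Series(0, index=per_year.index))
        c2 = per_year.get("C2", pd.Series(0, index=per_year.index))
        qualifying = int(((c1 >= 1) | (c2 >= 2)).sum())
        presence = int(((c1 + c2) >= 1).sum())
    else:
        qualifying = presence = 0

    last3 = range(period.end_year - 2, period.end_year + 1)
    repro_recent = any(y in last3 for y in repro_years)
    need = math.ceil(period.length_years / 2)

    if qualifying >= need or repro_recent:
        status = "Permanent"
        if qualifying < need:
            logger.debug("cell %s: Permanent by recent reproduction only", cell_id)
    elif presence >= 1:
        status = "Sporadic"
        if presence >= need and qualifying < need:
            # presence in >= half the years but no year meets the per-year
            # evidence bar: conservative status, logged
            logger.info(
                "cell %s period %s: presence in %d years without qualifying "
                "evidence; classified Sporadic",
                cell_id,
                period.label,
                presence,
            )
    else:
        status = "Absent"
    return CellPeriodStatus(
        cell_id=cell_id,
        period=period.label,
        status=status,
        qualifying_years=qualifying,
        presence_years=presence,
        reproduction_recent=repro_recent,
    )


def classify_grid(
    records: pd.DataFrame,
    grid: pd.DataFrame,
    periods=DEFAULT_PERIODS,
    reproduction_events: list[ReproductionEvent] | None = None,
) -> pd.DataFrame:
    """Classify every grid cell for every period.

    Records must already be SCALP- and independence-filtered. Reproduction
    events are assigned to the cell containing their centroid. Returns one
    row per (cell, period) with status and supporting counts.
    """
    recs = records.copy()
    recs["cell_id"] = assign_cells(grid, recs["x"], recs["y"]).to_numpy()
    recs = recs[recs["cell_id"].notna()]
    years = pd.to_datetime(recs["date"]).dt.year

    events = reproduction_events or []
    if events:
        ev_cells = assign_cells(
            grid, [e.centroid_x for e in events], [e.centroid_y for e in events]
        )
        events_by_cell: dict[str, list[ReproductionEvent]] = {}
        for e, cid in zip(events, ev_cells):
            if cid is not None:
                events_by_cell.setdefault(cid, []).append(e)
    else:
        events_by_cell = {}

    out = []
    for period in periods:
        in_period = recs[(years >= period.start_year) & (years <= period.end_year)]
        by_cell = dict(tuple(in_period.groupby("cell_id", sort=False)))
        for cid in grid["cell_id"]:
            cell_events = [
                e for e in events_by_cell.get(cid, []) if e.year in period.years
            ]
            st = classify_cell(
                by_cell.get(cid, in_period.iloc[0:0]), period, cell_events, cell_id=cid
            )
            out.append(st.__dict__)
    return pd.DataFrame(out)


def summarize_occupancy(statuses: pd.DataFrame) -> dict:
    """Per-period occupancy counts and between-period net increases.

    ``statuses`` is the classify_grid output (>= 2 periods). Net increase
    between the first and last period is ``100 * (c_last - c_first)/c_first``
    reported for Permanent, Sporadic and total occupied (Permanent+Sporadic);
    a zero baseline yields NaN with a warning.
    """
    period_labels = list(dict.fromkeys(statuses["period"]))
    if len(period_labels) < 2:
        raise ValueError("summarize_occupancy needs at least two periods")
    counts = {}
    for label in period_labels:
        sub = statuses[statuses["period"] == label]
        n_perm = int((sub["status"] == "Permanent").sum())
        n_spor = int((sub["status"] == "Sporadic").sum())
        counts[label] = {
            "n_permanent": n_perm,
            "n_sporadic": n_spor,
            "n_occupied": n_perm + n_spor,
        }

    def net(first: int, last: int, what: str) -> float:
        if first == 0:
            logger.warning("net increase for %s undefined (baseline 0)", what)
            return float("nan")
        return 100.0 * (last - first) / first

    first, last = counts[period_labels[0]], counts[period_labels[-1]]
    return {
        "counts": counts,
        "net_increase_permanent_pct": net(first["n_permanent"], last["n_permanent"], "Permanent"),
        "net_increase_sporadic_pct": net(first["n_sporadic"], last["n_sporadic"], "Sporadic"),
        "net_increase_total_pct": net(first["n_occupied"], last["n_occupied"], "occupied"),
    }


def grid_to_geojson(grid: pd.DataFrame, statuses: pd.DataFrame | None = None) -> dict:
    """Export the grid (optionally with per-period statuses) as GeoJSON.

    One polygon Feature per cell; status columns appear as properties named
    ``status_<period>``. Coordinates stay in the projected CRS of the grid.
    """
    props_by_cell: dict[str, dict] = {cid: {} for cid in grid["cell_id"]}
    if statuses is not None:
        for _, r in statuses.iterrows():
            props_by_cell[r["cell_id"]][f"status_{r['period']}"] = r["status"]
    features = []
    for _, c in grid.iterrows():
        geom = box(c["min_x"], c["min_y"], c["min_x"] + c["size"], c["min_y"] + c["size"])
        features.append(
            {
                "type": "Feature",
                "geometry": mapping(geom),
                "properties": {"cell_id": c["cell_id"], **props_by_cell[c["cell_id"]]},
            }
        )
    return {"type": "FeatureCollection", "features": features}


def write_geojson(path, grid: pd.DataFrame, statuses: pd.DataFrame | None = None) -> None:
    with open(path, "w") as fh:
        json.dump(grid_to_geojson(grid, statuses), fh)
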