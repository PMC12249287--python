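"""Occurrence records and the validity/independence filters applied before mapping.

An occurrence record is one verified wolf datum: a dated, georeferenced sign
(carcass, depredation, camera image, direct observation or scat) carrying a
SCALP reliability code (C1 hard evidence, C2 expert-confirmed, C3 unconfirmed)
and an optional reproduction flag (pup evidence).

Records travel as pandas DataFrames with the columns listed in
:data:`OCCURRENCE_COLUMNS`; coordinates are planar metres in a projected CRS
whose label is carried in configuration, never interpreted here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

SCALP_CODES = ("C1", "C2", "C3")
SOURCES = ("carcass", "depredation", "camera", "observation", "scat")

#: canonical column schema for occurrence CSV input
OCCURRENCE_COLUMNS = [
    "record_id",
    "date",
    "x",
    "y",
    "source",
    "scalp",
    "area_id",
    "is_reproduction",
]


@dataclass
class ReproductionEvent:
    """A unique reproduction: a same-year cluster of pup records.

    Two pup records belong to the same event when they fall in the same
    calendar year and are linked (directly or transitively) by pairwise
    planar distance strictly below the clustering threshold.
    """

    event_id: str
    year: int
    member_record_ids: list = field(default_factory=list)
    centroid_x: float = float("nan")
    centroid_y: float = float("nan")


def validate_occurrences(df: pd.DataFrame) -> pd.DataFrame:
    """Check the occurrence-record invariants and return the frame unchanged.

    Raises ``ValueError`` on an unknown SCALP code or non-finite coordinates;
    these indicate corrupted input rather than filterable data.
    """
    missing = [c for c in OCCURRENCE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"occurrence table missing columns: {missing}")
    bad_scalp = set(df["scalp"].dropna().unique()) - set(SCALP_CODES)
    if bad_scalp:
        raise ValueError(f"unknown SCALP codes: {sorted(bad_scalp)}")
    xy = df[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite coordinates in occurrence table")
    return df


def filter_scalp(df: pd.DataFrame) -> pd.DataFrame:
    """Drop unconfirmed (C3) occurrences, keeping C1 and C2 in input order.

    C3 data are unvalidated observations and are removed wholesale before any
    mapping or modeling; the operation is idempotent.
    """
    if len(df) == 0:
        return df.copy()
    bad = set(df["scalp"].dropna().unique()) - set(SCALP_CODES)
    if bad:
        raise ValueError(f"unknown SCALP codes: {sorted(bad)}")
    return df.loc[df["scalp"] != "C3"].copy()


def daily_independence(df: pd.DataFrame, area_key: str = "area_id") -> pd.DataFrame:
    """Retain at most one occurrence per area per day.

    Multiple same-day records in one area (e.g. several photos of the same
    pack) are not independent evidence; one representative is kept per
    (area, calendar day). The representative is the earliest by timestamp
    (column ``timestamp`` if present, else ``date``), ties broken by smallest
    ``record_id`` — a deterministic convention. Rows with missing dates are
    rejected with a logged warning. Input row order is preserved.
    """
    if len(df) == 0:
        return df.copy()
    dated = df[df["date"].notna()]
    n_dropped = len(df) - len(dated)
    if n_dropped:
        logger.warning("daily_independence: dropped %d records with missing date", n_dropped)
    if len(dated) == 0:
        return dated.copy()
    day = pd.to_datetime(dated["date"]).dt.normalize()
    ts = pd.to_datetime(dated["timestamp"]) if "timestamp" in dated.columns else pd.to_datetime(dated["date"])
    order = pd.DataFrame(
        {"_day": day, "_ts": ts, "_rid": dated["record_id"].astype(str)},
        index=dated.index,
    )
    keep_idx = (
        order.sort_values(["_ts", "_rid"], kind="mergesort")
        .groupby([dated[area_key], order["_day"]], sort=False)
        .head(1)
        .index
    )
    return dated.loc[dated.index.isin(keep_idx)].copy()


def camera_independence(
    detections: pd.DataFrame,
    window_minutes: float = 30.0,
    group_key=("site", "species"),
    rule: str = "rolling",
) -> pd.DataFrame:
    """Thin camera detections to independent events.

    Within each (site, species) group sorted by timestamp the first detection
    is retained; subsequent detections are discarded while they fall within
    ``window_minutes`` of the reference event. Grouping is at the monitoring
    *site* level (not single cameras) so that clustered cameras do not inflate
    detection rates.

    rule="rolling" (default): the reference is the last *retained* detection,
    so a retained event opens a fresh window. rule="previous": the reference
    is the immediately preceding detection whether retained or not, so a burst
    of images extends the window until a true gap appears. A detection is
    independent when its gap from the reference is strictly greater than the
    window.
    """
    if window_minutes < 0:
        raise ValueError("window_minutes must be non-negative")
    if rule not in ("rolling", "previous"):
        raise ValueError(f"unknown rule {rule!r}")
    if len(detections) == 0:
        return detections.copy()
    keys = [group_key] if isinstance(group_key, str) else list(group_key)
    ts = pd.to_datetime(detections["timestamp"])
    window = pd.Timedelta(minutes=window_minutes)

    keep_index: list = []
    for _, g in detections.assign(_ts=ts).groupby(keys, sort=False):
        g = g.sort_values("_ts", kind="mergesort")
        ref = None
        for idx, t in zip(g.index, g["_ts"]):
            if ref is None or t - ref > window:
                keep_index.append(idx)
                ref = t
            elif rule == "previous":
                ref = t  # burst extends the window
    keep = detections.index.isin(keep_index)
    return detections.loc[keep].copy()


def cluster_reproductions(
    pup_records: pd.DataFrame, threshold_m: float = 20_000.0
) -> list[ReproductionEvent]:
    """Group pup records into unique reproduction events.

    Within each calendar year, single-linkage clustering links two records
    when their planar distance is strictly below ``threshold_m`` (default
    20 km, a conservative pack spacing for a homogeneous landscape); each
    connected cluster is one event. Simultaneity is read as the calendar
    year — record counts per year are therefore the maximum number of
    distinct reproductions.
    """
    if len(pup_records) == 0:
        return []
    recs = pup_records
    if "is_reproduction" in recs.columns:
        if not recs["is_reproduction"].all():
            raise ValueError("cluster_reproductions expects records with is_reproduction=True")
    years = pd.to_datetime(recs["date"]).dt.year
    events: list[ReproductionEvent] = []
    for year in sorted(years.unique()):
        sub = recs.loc[years == year].sort_values("record_id", kind="mergesort")
        xy = sub[["x", "y"]].to_numpy(dtype=float)
        n = len(sub)
        # union-find keeps the strict < threshold link rule exact
        parent = list(range(n))

        def find(i: int) -> int:
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                if np.hypot(*(xy[i] - xy[j])) < threshold_m:
                    parent[find(i)] = find(j)
        labels = np.array([find(i) for i in range(n)])
        for k, lab in enumerate(np.unique(labels), start=1):
            members = sub.iloc[np.flatnonzero(labels == lab)]
            events.append(
                ReproductionEvent(
                    event_id=f"{year}-{k:02d}",
                    year=int(year),
                    member_record_ids=list(members["record_id"]),
                    centroid_x=float(members["x"].mean()),
                    centroid_y=float(members["y"].mean()),
                )
            )
    return events
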