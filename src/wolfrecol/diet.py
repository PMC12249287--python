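"""Scat-based diet composition: seasons, frequency of occurrence, Brillouin index.

Scats travel as a long-format DataFrame (one row per scat x food item) with
columns ``scat_id, date, item``. A taxonomy maps every item to one of five
fixed categories: livestock, wild prey, pet, fruit, other.

Frequency of occurrence (FO) of a unit (item or category) is the percentage
of scats containing it; its uncertainty is a bootstrap percentile interval
over resampled scats. Diet diversity is the Brillouin index

    HB = (ln N! - sum_i ln n_i!) / N

over pooled item counts; the accumulation curve of HB against the number of
scats, averaged over random orderings, gives the minimum sample size: the
point where the incremental change stays below 1%.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

CATEGORIES = ("livestock", "wild prey", "pet", "fruit", "other")

#: season start dates as (month, day); each season is half-open
#: [start, next-start)
SEASON_STARTS = {
    "spring": (3, 20),
    "summer": (6, 21),
    "fall": (9, 22),
    "winter": (12, 21),
}


def season_of(date) -> str:
    """Season of a collection date.

    Spring [20 Mar, 21 Jun), summer [21 Jun, 22 Sep), fall [22 Sep, 21 Dec),
    winter [21 Dec, 20 Mar); boundary dates belong to the starting season.
    """
    d = pd.Timestamp(date)
    md = (d.month, d.day)
    if SEASON_STARTS["spring"] <= md < SEASON_STARTS["summer"]:
        return "spring"
    if SEASON_STARTS["summer"] <= md < SEASON_STARTS["fall"]:
        return "summer"
    if SEASON_STARTS["fall"] <= md < SEASON_STARTS["winter"]:
        return "fall"
    return "winter"


def validate_taxonomy(taxonomy: dict) -> dict:
    bad = {i: c for i, c in taxonomy.items() if c not in CATEGORIES}
    if bad:
        raise ValueError(f"taxonomy entries outside the five categories: {bad}")
    return taxonomy


def _presence_matrix(scats: pd.DataFrame, taxonomy: dict, level: str) -> pd.DataFrame:
    """Boolean scats x units table; a repeated unit within a scat counts once."""
    if level not in ("item", "category"):
        raise ValueError(f"level must be 'item' or 'category', got {level!r}")
    unknown = sorted(set(scats["item"]) - set(taxonomy))
    if unknown:
        raise KeyError(f"items missing from taxonomy: {unknown}")
    unit = scats["item"] if level == "item" else scats["item"].map(taxonomy)
    return pd.crosstab(scats["scat_id"], unit).astype(bool)


def frequency_occurrence(
    scats: pd.DataFrame, taxonomy: dict, level: str = "category"
) -> pd.DataFrame:
    """Point FO per unit: ``100 * (#scats containing the unit) / N``.

    At category level a scat with two items of one category counts once.
    Returns a DataFrame with columns unit, n_scats, fo_percent, sorted by
    descending FO then unit name.
    """
    pres = _presence_matrix(scats, taxonomy, level)
    out = pd.DataFrame(
        {
            "unit": pres.columns,
            "n_scats": pres.sum(axis=0).to_numpy(),
            "fo_percent": 100.0 * pres.mean(axis=0).to_numpy(),
        }
    )
    return out.sort_values(["fo_percent", "unit"], ascending=[False, True]).reset_index(
        drop=True
    )


def bootstrap_fo_ci(
    scats: pd.DataFrame,
    taxonomy: dict,
    level: str = "category",
    B: int = 1000,
    conf: float = 0.95,
    seed: int | None = None,
) -> pd.DataFrame:
    """FO with bootstrap percentile confidence intervals.

    Resamples the N scats with replacement ``B`` times (default 1000) and
    takes the (1-conf)/2 and 1-(1-conf)/2 percentiles of the replicate FO
    values per unit. The seed makes the interval reproducible.
    """
    if B <= 0:
        raise ValueError("B must be positive")
    pres = _presence_matrix(scats, taxonomy, level)
    n = len(pres)
    if n < 2:
        raise ValueError("need at least 2 scats to bootstrap")
    rng = np.random.default_rng(seed)
    mat = pres.to_numpy(dtype=float)  # n x units
    idx = rng.integers(0, n, size=(B, n))
    replicates = 100.0 * mat[idx].mean(axis=1)  # B x units
    alpha = (1.0 - conf) / 2.0
    lo, hi = np.percentile(replicates, [100 * alpha, 100 * (1 - alpha)], axis=0)
    out = frequency_occurrence(scats, taxonomy, level)
    ci = pd.DataFrame({"unit": pres.columns, "ci_low": lo, "ci_high": hi})
    return out.merge(ci, on="unit")


def brillouin(item_counts) -> float:
    """Brillouin diversity index of pooled item counts.

    ``HB = (ln N! - sum ln n_i!) / N`` with ``N = sum n_i``, computed via
    log-gamma. Zero iff a single distinct item.
    """
    counts = np.asarray(item_counts, dtype=float)
    if counts.size == 0:
        raise ValueError("empty counts")
    if (counts < 1).any():
        raise ValueError("all counts must be >= 1")
    n = counts.sum()
    return float((gammaln(n + 1) - gammaln(counts + 1).sum()) / n)


@dataclass
class BrillouinCurve:
    """Averaged accumulation curve of HB against number of scats pooled."""

    k: np.ndarray  # 1..N
    hb: np.ndarray  # mean HB over orderings
    incremental_change: np.ndarray  # mean |dHB|/HB_{k-1} * 100, NaN at k=1
    min_sample: int | None  # smallest k with change < 1% thereafter


def min_sample_size(
    scats: pd.DataFrame,
    orderings: int = 100,
    seed: int | None = None,
    threshold_pct: float = 1.0,
    mode: str = "random",
) -> BrillouinCurve:
    """Minimum number of scats for a stable diet description.

    Scats are pooled one at a time; after each addition the Brillouin index
    of the pooled item counts and its absolute relative change (%) are
    recorded. With ``mode="random"`` the curve is averaged over random scat
    orderings (collection order is arbitrary); ``mode="collection"`` uses
    date order once. The minimum sample size is the smallest k at which the
    averaged change drops below ``threshold_pct`` *and stays below* for all
    larger k — a plain first crossing can fire spuriously early. ``None``
    (flagged) when the curve never stabilizes or HB is identically zero.
    """
    ids = list(dict.fromkeys(scats["scat_id"]))
    n = len(ids)
    if n < 3:
        raise ValueError("need at least 3 scats")
    items_by_scat = scats.groupby("scat_id", sort=False)["item"].apply(list).to_dict()
    item_codes = {it: j for j, it in enumerate(sorted(set(scats["item"])))}

    if mode == "collection":
        order_ids = (
            scats[["scat_id", "date"]]
            .drop_duplicates("scat_id")
            .sort_values(["date", "scat_id"], kind="mergesort")["scat_id"]
            .tolist()
        )
        orders = [order_ids]
    elif mode == "random":
        rng = np.random.default_rng(seed)
        orders = [list(rng.permutation(ids)) for _ in range(orderings)]
    else:
        raise ValueError(f"unknown mode {mode!r}")

    hb_all = np.zeros((len(orders), n))
    chg_all = np.full((len(orders), n), np.nan)
    for oi, order in enumerate(orders):
        counts = np.zeros(len(item_codes))
        prev = None
        for k, sid in enumerate(order, start=1):
            for it in items_by_scat[sid]:
                counts[item_codes[it]] += 1
            present = counts[counts > 0]
            hb = brillouin(present)
            hb_all[oi, k - 1] = hb
            if prev is not None and prev > 0:
                chg_all[oi, k - 1] = abs(hb - prev) / prev * 100.0
            prev = hb

    hb_mean = hb_all.mean(axis=0)
    with warnings.catch_warnings():
        # k=1 has no increment by construction; all-NaN column is expected
        warnings.simplefilter("ignore", RuntimeWarning)
        chg_mean = np.nanmean(chg_all, axis=0)

    min_sample: int | None = None
    valid = ~np.isnan(chg_mean)
    below = np.where(valid, chg_mean < threshold_pct, False)
    # smallest k (>=2) below threshold with every later valid k also below
    for k in range(2, n + 1):
        i = k - 1
        if not valid[i] or not below[i]:
            continue
        if all(below[j] or not valid[j] for j in range(i, n)):
            min_sample = k
            break
    return BrillouinCurve(
        k=np.arange(1, n + 1), hb=hb_mean, incremental_change=chg_mean, min_sample=min_sample
    )


def monthly_survey_distance_km(n_transects: int, mean_length_m: float) -> float:
    """Distance walked per monthly survey round, in km (2 decimals)."""
    if n_transects <= 0 or mean_length_m <= 0:
        raise ValueError("transect count and length must be positive")
    return round(n_transects * mean_length_m / 1000.0, 2)


def assign_seasons(scats: pd.DataFrame) -> pd.DataFrame:
    """Add a ``season`` column derived from each scat's collection date."""
    out = scats.copy()
    out["season"] = pd.to_datetime(out["date"]).map(season_of)
    return out
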