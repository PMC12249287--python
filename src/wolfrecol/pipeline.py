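"""End-to-end orchestration: simulate/load -> filter -> occupancy -> activity
-> diet -> models, with per-stage CSV/GeoJSON outputs and a JSON summary.

The pipeline is configured by a flat dictionary (typically read from YAML);
unknown keys are rejected up front so typos fail fast. Every stage is a pure
function over DataFrames from the sibling modules; this module only sequences
them and handles I/O, so each stage is independently re-runnable from files.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, activity, diet, grid, models, records, simulate

logger = logging.getLogger(__name__)

DEFAULT_CONFIG = {
    "seed": 0,
    "simulate": True,
    "outdir": "results",
    "crs": "EPSG:32633",
    "cell_size_m": 10_000.0,
    "periods": [
        {"label": "2015-2019", "start_year": 2015, "end_year": 2019},
        {"label": "2020-2024", "start_year": 2020, "end_year": 2024},
    ],
    "camera_window_minutes": 30,
    "camera_rule": "rolling",
    "reproduction_threshold_m": 20_000.0,
    "bootstrap_replicates": 1000,
    "bootstrap_conf": 0.95,
    "brillouin_orderings": 100,
    "kde_adjust": 1.0,
    "inputs": {},  # occurrences/camera_detections/scats/covariates/taxonomy paths
}


def load_config(path=None, overrides: dict | None = None) -> dict:
    """Merge YAML config over defaults; reject unknown keys."""
    cfg = {k: (dict(v) if isinstance(v, dict) else v) for k, v in DEFAULT_CONFIG.items()}
    user = {}
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
    user.update(overrides or {})
    unknown = set(user) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(user)
    return cfg


def config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:12]


def _periods(cfg: dict) -> tuple[grid.Period, ...]:
    return tuple(
        grid.Period(p["label"], int(p["start_year"]), int(p["end_year"]))
        for p in cfg["periods"]
    )


def _load_inputs(cfg: dict) -> dict:
    if cfg["simulate"]:
        sim = simulate.SimulationConfig(seed=int(cfg["seed"]))
        data = simulate.simulate_all(sim)
        data.pop("config")
        return data
    paths = cfg["inputs"]
    needed = {"occurrences", "camera_detections", "scats", "covariates", "taxonomy"}
    missing = needed - set(paths)
    if missing:
        raise ValueError(f"simulate=false but input paths missing: {sorted(missing)}")
    occ = pd.read_csv(paths["occurrences"], parse_dates=["date"])
    cams = pd.read_csv(paths["camera_detections"], parse_dates=["timestamp"])
    scats = pd.read_csv(paths["scats"], parse_dates=["date"])
    cov = pd.read_csv(paths["covariates"])
    with open(paths["taxonomy"]) as fh:
        taxonomy = yaml.safe_load(fh)
    extent = (
        occ["x"].min(),
        occ["y"].min(),
        occ["x"].max() + 1.0,
        occ["y"].max() + 1.0,
    )
    g = grid.build_grid(extent, float(cfg["cell_size_m"]))
    return {
        "grid": g,
        "covariates": cov,
        "occurrences": occ,
        "camera_detections": cams,
        "scats": scats,
        "taxonomy": taxonomy,
    }


def run_pipeline(cfg: dict | None = None, config_path=None) -> dict:
    """Run every stage and write outputs under ``cfg['outdir']``.

    Returns the summary dict (occupancy counts and net increases, pairwise
    overlap with classes, diet FO table with CIs, the model-ranking head and
    averaged coefficients) that is also written as ``summary.json``.
    """
    cfg = cfg if cfg is not None else load_config(config_path)
    outdir = Path(cfg["outdir"])
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(cfg)
    data = _load_inputs(cfg)

    # --- filtering -------------------------------------------------------
    occ = records.validate_occurrences(data["occurrences"])
    occ = records.filter_scalp(occ)
    occ = records.daily_independence(occ)
    occ.to_csv(outdir / "occurrences_filtered.csv", index=False)

    cams = records.camera_independence(
        data["camera_detections"],
        window_minutes=float(cfg["camera_window_minutes"]),
        rule=cfg["camera_rule"],
    )
    cams.to_csv(outdir / "camera_independent.csv", index=False)

    # --- occupancy -------------------------------------------------------
    periods = _periods(cfg)
    events = records.cluster_reproductions(
        occ[occ["is_reproduction"]], threshold_m=float(cfg["reproduction_threshold_m"])
    )
    statuses = grid.classify_grid(occ, data["grid"], periods, events)
    statuses.to_csv(outdir / "cell_status.csv", index=False)
    grid.write_geojson(outdir / "grid_status.geojson", data["grid"], statuses)
    occupancy = grid.summarize_occupancy(statuses)
    # unique reproductions per period: the max number of distinct events in
    # any one year of the period
    events_per_year: dict[int, int] = {}
    for e in events:
        events_per_year[e.year] = events_per_year.get(e.year, 0) + 1
    occupancy["unique_reproductions"] = {
        p.label: max((events_per_year.get(y, 0) for y in p.years), default=0)
        for p in periods
    }

    # --- activity overlap ------------------------------------------------
    pairs = []
    focal = "wolf"
    for site, site_df in cams.groupby("site", sort=False):
        series = {
            sp: activity.hours_to_radians(
                pd.to_datetime(g["timestamp"]).dt.hour
                + pd.to_datetime(g["timestamp"]).dt.minute / 60.0
            )
            for sp, g in site_df.groupby("species", sort=False)
        }
        if focal not in series:
            continue
        for sp, t in series.items():
            if sp == focal or len(t) < 2 or len(series[focal]) < 2:
                continue
            try:
                res = activity.delta4(series[focal], t, adjust=float(cfg["kde_adjust"]))
            except ValueError as exc:
                logger.warning("overlap %s/%s at %s skipped: %s", focal, sp, site, exc)
                continue
            pairs.append(
                {
                    "site": site,
                    "species_a": focal,
                    "species_b": sp,
                    "n_a": res.n1,
                    "n_b": res.n2,
                    "delta4": res.delta4,
                    "delta1_oracle": res.delta1_oracle,
                    "class": res.overlap_class,
                }
            )
    overlap_df = pd.DataFrame(pairs)
    overlap_df.to_csv(outdir / "overlap.csv", index=False)

    rai_rows = [
        {
            "site": site,
            "species": sp,
            "detections": len(g),
            "trap_nights": simulate.SimulationConfig().trap_nights.get(site, np.nan),
        }
        for (site, sp), g in cams.groupby(["site", "species"], sort=False)
    ]
    rai_df = pd.DataFrame(rai_rows)
    rai_df["rai"] = [
        activity.rai(d, t) if t == t and t > 0 else np.nan
        for d, t in zip(rai_df["detections"], rai_df["trap_nights"])
    ]
    rai_df.to_csv(outdir / "rai.csv", index=False)

    # --- diet ------------------------------------------------------------
    scats = diet.assign_seasons(data["scats"])
    taxonomy = diet.validate_taxonomy(data["taxonomy"])
    fo_cat = diet.bootstrap_fo_ci(
        scats,
        taxonomy,
        level="category",
        B=int(cfg["bootstrap_replicates"]),
        conf=float(cfg["bootstrap_conf"]),
        seed=int(cfg["seed"]),
    )
    fo_item = diet.bootstrap_fo_ci(
        scats,
        taxonomy,
        level="item",
        B=int(cfg["bootstrap_replicates"]),
        conf=float(cfg["bootstrap_conf"]),
        seed=int(cfg["seed"]),
    )
    fo_cat.to_csv(outdir / "diet_fo_category.csv", index=False)
    fo_item.to_csv(outdir / "diet_fo_item.csv", index=False)
    curve = diet.min_sample_size(
        scats, orderings=int(cfg["brillouin_orderings"]), seed=int(cfg["seed"])
    )
    pd.DataFrame(
        {"k": curve.k, "hb": curve.hb, "incremental_change_pct": curve.incremental_change}
    ).to_csv(outdir / "brillouin_curve.csv", index=False)

    # --- model selection -------------------------------------------------
    status2 = statuses[statuses["period"] == periods[-1].label]
    occupied = status2[status2["status"].isin(["Permanent", "Sporadic"])]
    table = occupied.merge(data["covariates"], on="cell_id")
    table["status"] = (table["status"] == "Permanent").astype(int)
    covnames = [c for c in data["covariates"].columns if c != "cell_id"]
    model_summary: dict = {"n_cells": int(len(table))}
    if len(table) >= 10 and table["status"].nunique() == 2:
        ranking = models.fit_all_subsets(table, covnames)
        rank_tbl = ranking.table()
        rank_tbl.to_csv(outdir / "model_ranking.csv", index=False)
        averaged = models.average_models(ranking)
        pd.DataFrame(averaged.items(), columns=["term", "coefficient"]).to_csv(
            outdir / "model_averaged.csv", index=False
        )
        model_summary.update(
            {
                "n_models": int(len(ranking.fits)),
                "best_model": ranking.fits[0].name,
                "best_weight": float(ranking.weights[0]),
                "n_competitors": int(len(ranking.competitors)),
                "averaged_coefficients": averaged,
            }
        )
    else:
        logger.warning("model selection skipped: too few classified cells")

    summary = {
        "version": __version__,
        "config_hash": chash,
        "seed": int(cfg["seed"]),
        "n_occurrences_filtered": int(len(occ)),
        "n_reproduction_events": int(len(events)),
        "occupancy": occupancy,
        "overlap": pairs,
        "diet_fo_category": fo_cat.to_dict(orient="records"),
        "brillouin_min_sample": curve.min_sample,
        "models": model_summary,
    }
    with open(outdir / "summary.json", "w") as fh:
        json.dump(summary, fh, indent=2, default=float)
    with open(outdir / "run_config.yaml", "w") as fh:
        yaml.safe_dump({**cfg, "config_hash": chash}, fh)
    return summary
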