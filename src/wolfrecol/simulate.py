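"""Synthetic data with the statistical structure the analysis assumes.

No field data ship with this package, so every pipeline input is generated:

* per-cell landscape covariates drawn within realistic ranges (road density
  1.4-5.9 km/km2, 7-40 forest patches, ...), with total forested area derived
  from forest percentage so the collinearity screen has a genuine offender;
* multi-year occurrence records whose per-cell intensity follows a logistic
  model on the covariates, with configurable SCALP code proportions and
  reproduction flags placed in the highest-intensity cells;
* diel detection times from von Mises mixtures (nocturnal, crepuscular and
  diurnal presets);
* multinomial scat contents over a fixed item -> category taxonomy.

The default configuration is "study-like": magnitudes match the monitored
system (two 5-year periods, 3 camera sites, 1402 trap nights, 75 scats)
without claiming to reproduce the real data. One master seed fans out to
per-generator child seeds through ``numpy.random.SeedSequence.spawn`` in a
fixed documented order (covariates, occurrences, activity, scats), so each
generator is independently reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .grid import DEFAULT_PERIODS, Period, build_grid

#: fan-out order of child seeds from the master seed
SEED_CHILDREN = ("covariates", "occurrences", "activity", "scats", "status")

#: default item -> category taxonomy used by generated scats
DEFAULT_TAXONOMY = {
    "sheep": "livestock",
    "goat": "livestock",
    "cattle": "livestock",
    "dog": "pet",
    "cat": "pet",
    "red fox": "wild prey",
    "badger": "wild prey",
    "beech marten": "wild prey",
    "wild boar": "wild prey",
    "hare": "wild prey",
    "bird": "other",
    "rodent": "other",
    "insect": "other",
    "fruit pulp": "fruit",
    "olive": "fruit",
}

#: default per-item draw probabilities, shaped like a livestock-heavy,
#: low-wild-ungulate diet (sheep and dog dominant, fox/bird frequent)
DEFAULT_ITEM_PROBS = {
    "sheep": 0.21,
    "goat": 0.06,
    "cattle": 0.03,
    "dog": 0.17,
    "cat": 0.05,
    "red fox": 0.12,
    "badger": 0.04,
    "beech marten": 0.03,
    "wild boar": 0.04,
    "hare": 0.04,
    "bird": 0.12,
    "rodent": 0.03,
    "insect": 0.02,
    "fruit pulp": 0.03,
    "olive": 0.01,
}

#: von Mises mixture presets (component means in hours, kappas, weights)
ACTIVITY_PRESETS = {
    "nocturnal": ((22.0, 4.0), (2.0, 2.0), (0.5, 0.5)),
    "crepuscular": ((6.0, 19.0), (3.0, 3.0), (0.5, 0.5)),
    "diurnal": ((13.0,), (2.0,), (1.0,)),
    "cathemeral": ((2.0, 14.0), (0.8, 0.5), (0.6, 0.4)),
}

#: covariate sampling ranges (uniform), magnitudes from the monitored system
DEFAULT_COVARIATE_RANGES = {
    "road_density": (1.3, 5.9),  # km/km2
    "n_farms": (0, 36),  # ovicaprine farms per cell (integer)
    "pa_perc": (0.0, 8.5),  # % protected area
    "forest_perc": (0.7, 37.0),  # % forested cover
    "forest_count": (7, 40),  # forest patches per cell (integer)
}


@dataclass
class SimulationConfig:
    """Study-like defaults for every generator; one master seed rules all."""

    seed: int = 0
    extent: tuple[float, float, float, float] = (0.0, 0.0, 50_000.0, 90_000.0)
    cell_size: float = 10_000.0
    periods: tuple[Period, ...] = DEFAULT_PERIODS
    # logistic link from standardized covariates to occurrence intensity
    beta: dict = field(
        default_factory=lambda: {
            "intercept": -1.0,
            "road_density": 0.0,
            "n_farms": 0.0,
            "pa_perc": 0.3,
            "forest_perc": 0.4,
            "forest_count": 1.2,
        }
    )
    base_rate: float = 0.15  # first-year mean records for a fully suitable cell
    growth: float = 1.35  # yearly intensity multiplier (ongoing recolonization)
    scalp_probs: tuple[float, float, float] = (0.85, 0.08, 0.07)  # C1, C2, C3
    n_reproduction_cells: int = 4
    # camera trapping: per-site trap nights as monitored
    trap_nights: dict = field(default_factory=lambda: {"Site 1": 732, "Site 2": 480, "Site 3": 190})
    n_scats: int = 75
    items_per_scat_probs: tuple[float, ...] = (0.55, 0.35, 0.10)  # P(1), P(2), P(3)


def child_seeds(master_seed: int) -> dict[str, np.random.SeedSequence]:
    """Named child seed sequences in the documented fan-out order."""
    children = np.random.SeedSequence(master_seed).spawn(len(SEED_CHILDREN))
    return dict(zip(SEED_CHILDREN, children))


def _rng_for(master_seed: int, name: str) -> np.random.Generator:
    return np.random.default_rng(child_seeds(master_seed)[name])


def gen_covariates(
    grid: pd.DataFrame,
    seed: int,
    ranges: dict | None = None,
) -> pd.DataFrame:
    """Per-cell landscape covariates within configured ranges.

    Integer-valued covariates (farm and patch counts) are drawn as integers.
    ``forest_area`` (km2) loads on both forest percentage and patch count —
    in a fragmented landscape total forested area is redundant with the two
    of them together — so the collinearity screen has a genuine hub covariate
    to remove, as a real total-area covariate would be.
    """
    rng = _rng_for(seed, "covariates")
    ranges = ranges or DEFAULT_COVARIATE_RANGES
    n = len(grid)
    cov = pd.DataFrame({"cell_id": grid["cell_id"]})
    for name, (lo, hi) in ranges.items():
        if isinstance(lo, int) and isinstance(hi, int):
            cov[name] = rng.integers(lo, hi + 1, size=n)
        else:
            cov[name] = rng.uniform(lo, hi, size=n)

    def z(col):
        v = cov[col].to_numpy(dtype=float)
        return (v - v.mean()) / v.std()

    latent = 0.8 * z("forest_perc") + 0.45 * z("forest_count") + 0.12 * rng.standard_normal(n)
    cov["forest_area"] = np.maximum(0.3, 8.0 + 6.0 * latent / np.sqrt(0.8**2 + 0.45**2 + 0.12**2))
    return cov


def logistic_scores(covariates: pd.DataFrame, beta: dict) -> np.ndarray:
    """P(high suitability) per cell: logit on standardized covariates."""
    eta = np.full(len(covariates), float(beta.get("intercept", 0.0)))
    for name, b in beta.items():
        if name == "intercept" or b == 0.0:
            continue
        col = covariates[name].to_numpy(dtype=float)
        sd = col.std()
        z = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        eta += b * z
    return 1.0 / (1.0 + np.exp(-eta))


def gen_occurrences(
    grid: pd.DataFrame,
    covariates: pd.DataFrame,
    seed: int,
    beta: dict | None = None,
    years: range = range(2015, 2025),
    base_rate: float = 0.15,
    growth: float = 1.35,
    scalp_probs: tuple[float, float, float] = (0.85, 0.08, 0.07),
    n_reproduction_cells: int = 4,
) -> pd.DataFrame:
    """Multi-year occurrence records with covariate-linked intensity.

    Per cell-year, record counts are Poisson with mean
    ``base_rate * growth**(year - first_year) * p_cell`` where ``p_cell`` is
    the cell's logistic suitability score — intensity rises in the better
    cells and grows year over year, emulating an ongoing recolonization.
    Locations are uniform within the cell, SCALP codes multinomial with the
    configured proportions, and sources a fixed opportunistic mix.
    Reproduction flags go to the ``n_reproduction_cells`` highest-scoring
    cells in the later half of the years, one pup record per flagged
    cell-year.
    """
    cfg_beta = beta or SimulationConfig().beta
    rng = _rng_for(seed, "occurrences")
    p = logistic_scores(covariates, cfg_beta)
    size = float(grid["size"].iloc[0])
    sources = np.array(["carcass", "depredation", "camera", "observation", "scat"])
    source_probs = np.array([0.10, 0.15, 0.55, 0.12, 0.08])

    top_cells = set(
        covariates.loc[np.argsort(p)[::-1][:n_reproduction_cells], "cell_id"]
    )
    rows = []
    rid = 0
    for (_, cell), pc in zip(grid.iterrows(), p):
        for year in years:
            lam = base_rate * growth ** (year - years[0]) * pc
            n_rec = rng.poisson(lam)
            for _ in range(n_rec):
                rid += 1
                day = rng.integers(0, 365)
                rows.append(
                    {
                        "record_id": f"occ{rid:06d}",
                        "date": (pd.Timestamp(f"{year}-01-01") + pd.Timedelta(days=int(day))),
                        "x": cell["min_x"] + rng.uniform(0, size),
                        "y": cell["min_y"] + rng.uniform(0, size),
                        "source": rng.choice(sources, p=source_probs),
                        "scalp": rng.choice(["C1", "C2", "C3"], p=list(scalp_probs)),
                        "area_id": cell["cell_id"],
                        "is_reproduction": False,
                    }
                )
            if cell["cell_id"] in top_cells and year >= years[len(years) // 2]:
                rid += 1
                rows.append(
                    {
                        "record_id": f"occ{rid:06d}",
                        "date": pd.Timestamp(f"{year}-06-15"),
                        "x": cell["min_x"] + size / 2,
                        "y": cell["min_y"] + size / 2,
                        "source": "camera",
                        "scalp": "C1",
                        "area_id": cell["cell_id"],
                        "is_reproduction": True,
                    }
                )
    df = pd.DataFrame(rows)
    if len(df) == 0:
        df = pd.DataFrame(columns=["record_id", "date", "x", "y", "source", "scalp", "area_id", "is_reproduction"])
    return df


def gen_activity(
    n: int,
    mixture: str | tuple = "nocturnal",
    seed: int = 0,
    species: str = "wolf",
    site: str = "Site 1",
):
    """Draw detection times (radians) from a von Mises mixture.

    ``mixture`` is a preset name or a ``(means_hours, kappas, weights)``
    triple. Returns a :class:`wolfrecol.activity.DetectionSeries`.
    """
    from .activity import TWO_PI, DetectionSeries, hours_to_radians

    if isinstance(mixture, str):
        mixture = ACTIVITY_PRESETS[mixture]
    means_h, kappas, weights = mixture
    w = np.asarray(weights, dtype=float)
    if not np.isclose(w.sum(), 1.0):
        raise ValueError("mixture weights must sum to 1")
    rng = _rng_for(seed, "activity")
    comp = rng.choice(len(w), size=n, p=w)
    mus = hours_to_radians(np.asarray(means_h, dtype=float))
    times = np.array(
        [rng.vonmises(mus[c], kappas[c]) for c in comp]
    ) % TWO_PI
    return DetectionSeries(species=species, site=site, times=times)


def gen_scats(
    n: int = 75,
    item_probs: dict | None = None,
    items_per_scat_probs: tuple[float, ...] = (0.55, 0.35, 0.10),
    seed: int = 0,
    start: str = "2024-06-01",
    end: str = "2024-12-31",
) -> pd.DataFrame:
    """Long-format scat table: one row per (scat, item).

    Each scat draws its item count from ``items_per_scat_probs`` (1, 2, 3
    items) and then that many distinct items with probability proportional
    to ``item_probs``; collection dates are uniform over [start, end].
    """
    probs = item_probs or DEFAULT_ITEM_PROBS
    items = np.array(list(probs))
    pvec = np.array([probs[i] for i in items], dtype=float)
    if (pvec < 0).any() or pvec.sum() <= 0:
        raise ValueError("invalid item probabilities")
    pvec = pvec / pvec.sum()
    kprobs = np.asarray(items_per_scat_probs, dtype=float)
    if not np.isclose(kprobs.sum(), 1.0):
        raise ValueError("items_per_scat_probs must sum to 1")
    rng = _rng_for(seed, "scats")
    t0, t1 = pd.Timestamp(start), pd.Timestamp(end)
    span_days = (t1 - t0).days
    rows = []
    for s in range(1, n + 1):
        k = rng.choice(len(kprobs), p=kprobs) + 1
        k = min(k, len(items))
        chosen = rng.choice(items, size=k, replace=False, p=pvec)
        date = t0 + pd.Timedelta(days=int(rng.integers(0, span_days + 1)))
        for it in chosen:
            rows.append({"scat_id": f"scat{s:03d}", "date": date, "item": it})
    return pd.DataFrame(rows)


def gen_status_table(
    covariates: pd.DataFrame, beta: dict, seed: int
) -> pd.DataFrame:
    """Binary status table with known coefficients, for parameter recovery.

    Draws ``status ~ Bernoulli(sigmoid(beta . z))`` on the standardized
    covariates — the generating model is exactly the logistic model the
    selection module fits, so refitting should recover ``beta`` up to
    sampling error.
    """
    rng = _rng_for(seed, "status")
    p = logistic_scores(covariates, beta)
    out = covariates.copy()
    out["status"] = rng.binomial(1, p)
    return out


def simulate_all(config: SimulationConfig | None = None) -> dict:
    """Generate every pipeline input from one configuration.

    Returns a dict with the grid, covariates, occurrence records, per-species
    camera detection logs (wolf, red fox, badger, wild boar, human), the scat
    table and the taxonomy.
    """
    cfg = config or SimulationConfig()
    grid = build_grid(cfg.extent, cfg.cell_size)
    cov = gen_covariates(grid, cfg.seed)
    occ = gen_occurrences(
        grid,
        cov,
        cfg.seed,
        beta=cfg.beta,
        years=range(cfg.periods[0].start_year, cfg.periods[-1].end_year + 1),
        base_rate=cfg.base_rate,
        growth=cfg.growth,
        scalp_probs=cfg.scalp_probs,
        n_reproduction_cells=cfg.n_reproduction_cells,
    )
    species_presets = {
        "wolf": "nocturnal",
        "red fox": "nocturnal",
        "badger": "crepuscular",
        "wild boar": "diurnal",
        "human": "diurnal",
    }
    rng = _rng_for(cfg.seed, "activity")
    detections = []
    for site, nights in cfg.trap_nights.items():
        for sp_i, (sp, preset) in enumerate(species_presets.items()):
            n_det = max(80, int(nights * 0.4))
            series = gen_activity(
                n_det, preset, seed=cfg.seed + 7919 * (sp_i + 1), species=sp, site=site
            )
            day = rng.integers(0, nights, size=n_det)
            hours = series.times * 24.0 / (2 * np.pi)
            ts = pd.Timestamp("2023-01-01") + pd.to_timedelta(day, "D") + pd.to_timedelta(hours, "h")
            detections.append(
                pd.DataFrame({"site": site, "species": sp, "timestamp": ts})
            )
    cams = pd.concat(detections, ignore_index=True).sort_values(
        ["site", "species", "timestamp"], kind="mergesort"
    ).reset_index(drop=True)
    scats = gen_scats(
        cfg.n_scats,
        items_per_scat_probs=cfg.items_per_scat_probs,
        seed=cfg.seed,
    )
    return {
        "config": cfg,
        "grid": grid,
        "covariates": cov,
        "occurrences": occ,
        "camera_detections": cams,
        "scats": scats,
        "taxonomy": dict(DEFAULT_TAXONOMY),
    }
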