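"""All-subsets binomial GLMs of cell status: screening, AICc ranking, averaging.

The occupancy model asks which landscape covariates separate Permanent (1)
from Sporadic (0) grid cells. The workflow is the standard
information-theoretic one:

1. screen covariates for collinearity (drop one of each pair with Pearson
   |r| above 0.7);
2. fit logistic regressions for every subset of the retained covariates
   (2^p models including the intercept-only null);
3. rank by AICc, ``AICc = AIC + 2k(k+1)/(n-k-1)``, compute ``Delta_i`` and
   Akaike weights ``w_i = exp(-Delta_i/2) / sum_j exp(-Delta_j/2)`` over all
   candidates;
4. average coefficients over the competitor set (Delta < 2), weights
   renormalized there.

Model fitting itself is delegated to statsmodels (Binomial GLM, logit link,
IRLS); everything information-theoretic is computed here.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

logger = logging.getLogger(__name__)

#: |Pearson r| above which two covariates are considered collinear
COLLINEARITY_THRESHOLD = 0.7
#: Delta-AICc below which a model competes with the best
COMPETITOR_DELTA = 2.0
#: |coefficient| beyond which a logistic fit is flagged as separated
SEPARATION_BETA = 50.0


def collinearity_screen(
    table: pd.DataFrame,
    covariates: list[str] | None = None,
    threshold: float = COLLINEARITY_THRESHOLD,
) -> list[str]:
    """Iteratively drop collinear covariates until all pairwise |r| <= threshold.

    From the worst offending pair, the covariate with the larger mean |r|
    against all remaining covariates is dropped (ties alphabetical) — it is
    the more redundant of the two. Constant covariates (undefined r) are
    dropped first with a warning. Returns the retained names in input order.
    """
    cols = list(covariates) if covariates is not None else list(table.columns)
    if len(cols) < 2:
        raise ValueError("need at least 2 covariates")
    if len(table) < 3:
        raise ValueError("need at least 3 rows")
    kept = []
    for c in cols:
        if table[c].nunique() <= 1:
            warnings.warn(f"covariate {c!r} is constant; dropped (r undefined)")
        else:
            kept.append(c)
    while len(kept) > 1:
        r = table[kept].corr(method="pearson").abs()
        np.fill_diagonal(r.values, 0.0)
        worst = r.stack().idxmax()
        if r.loc[worst] <= threshold:
            break
        a, b = sorted(worst)
        mean_r = r.mean(axis=0)  # diagonal zeroed; relative order is what matters
        if mean_r[a] > mean_r[b]:
            drop = a
        elif mean_r[b] > mean_r[a]:
            drop = b
        else:
            drop = min(a, b)
        logger.info("collinearity: dropping %r (|r|=%.3f with %r)", drop, r.loc[worst], a if drop == b else b)
        kept.remove(drop)
    return kept


def enumerate_models(covariates: list[str]) -> list[tuple[str, ...]]:
    """All subsets of the covariates (including the intercept-only model)."""
    p = len(covariates)
    if p > 20:
        raise ValueError(f"{p} covariates would give {2**p} models; refusing")
    return [
        tuple(s)
        for r in range(p + 1)
        for s in itertools.combinations(covariates, r)
    ]


@dataclass
class ModelFit:
    """One fitted logistic model with its information-criterion bookkeeping."""

    terms: tuple[str, ...]
    coefficients: dict[str, float]
    loglik: float
    k: int  # estimated parameters incl. intercept
    n: int
    aic: float
    aicc: float
    converged: bool = True
    separation: bool = False

    @property
    def name(self) -> str:
        return " + ".join(self.terms) if self.terms else "(intercept)"


def aicc_from_loglik(loglik: float, k: int, n: int) -> float:
    """Small-sample AIC: ``-2*logLik + 2k + 2k(k+1)/(n-k-1)``."""
    if n - k - 1 <= 0:
        raise ValueError(f"AICc undefined for n={n}, k={k} (n-k-1 <= 0)")
    aic = -2.0 * loglik + 2.0 * k
    return aic + 2.0 * k * (k + 1) / (n - k - 1)


def fit_logistic(
    table: pd.DataFrame, terms: tuple[str, ...] | list[str], response: str = "status"
) -> ModelFit:
    """Fit one binomial GLM (logit link) and report logLik/AIC/AICc.

    The response is binary (1 = Permanent, 0 = Sporadic). Quasi-complete
    separation is detected by a diverging coefficient (|beta| > 50) or a
    failed IRLS convergence and flagged on the returned fit; flagged fits are
    excluded from ranking downstream.
    """
    terms = tuple(terms)
    y = table[response].to_numpy(dtype=float)
    if not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("response must be binary 0/1")
    X = sm.add_constant(table[list(terms)], has_constant="add") if terms else pd.DataFrame(
        {"const": np.ones(len(table))}, index=table.index
    )
    n, k = len(table), len(terms) + 1
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # statsmodels warns on perfect separation
        res = sm.GLM(y, X, family=sm.families.Binomial()).fit()
    params = dict(zip(X.columns, res.params))
    mu = np.asarray(res.fittedvalues)
    # no finite MLE under (quasi-)complete separation: coefficients diverge
    # and fitted probabilities reach the observed 0/1 labels
    separated = (
        (not res.converged)
        or any(abs(b) > SEPARATION_BETA for b in params.values())
        or float(np.max(np.abs(mu - y))) < 1e-3
    )
    if separated:
        warnings.warn(f"possible separation in model {terms}; fit flagged")
    loglik = float(res.llf)
    return ModelFit(
        terms=terms,
        coefficients={("intercept" if c == "const" else c): float(b) for c, b in params.items()},
        loglik=loglik,
        k=k,
        n=n,
        aic=-2.0 * loglik + 2.0 * k,
        aicc=aicc_from_loglik(loglik, k, n),
        converged=bool(res.converged),
        separation=separated,
    )


@dataclass
class ModelRanking:
    """Candidate fits sorted by AICc with Delta and Akaike weights."""

    fits: list[ModelFit]
    delta: np.ndarray
    weights: np.ndarray
    competitors: list[ModelFit] = field(default_factory=list)

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "model": [f.name for f in self.fits],
                "df": [f.k for f in self.fits],
                "logLik": [f.loglik for f in self.fits],
                "AICc": [f.aicc for f in self.fits],
                "delta_AICc": self.delta,
                "weight": self.weights,
            }
        )


def rank_and_weight(fits: list[ModelFit]) -> ModelRanking:
    """Sort by AICc, compute Delta and Akaike weights over all candidates.

    Separation-flagged fits are excluded (with a warning). The competitor
    set is every model with Delta < 2 — models statistically indistinguishable
    from the best.
    """
    valid = [f for f in fits if not f.separation]
    n_bad = len(fits) - len(valid)
    if n_bad:
        warnings.warn(f"excluded {n_bad} separated fit(s) from ranking")
    if not valid:
        raise ValueError("no valid fits to rank")
    valid = sorted(valid, key=lambda f: f.aicc)
    aicc = np.array([f.aicc for f in valid])
    delta = aicc - aicc.min()
    rel = np.exp(-delta / 2.0)
    weights = rel / rel.sum()
    competitors = [f for f, d in zip(valid, delta) if d < COMPETITOR_DELTA]
    return ModelRanking(fits=valid, delta=delta, weights=weights, competitors=competitors)


def average_models(
    ranking: ModelRanking, method: str = "full"
) -> dict[str, float]:
    """Model-averaged coefficients over the competitor set (Delta < 2).

    Weights are renormalized over the competitors. With ``method="full"``
    a term absent from a model contributes beta = 0 (shrinks averaged effects
    toward zero); ``method="conditional"`` averages each term only over the
    models that contain it. A single competitor returns its coefficients
    unchanged.
    """
    if method not in ("full", "conditional"):
        raise ValueError(f"unknown averaging method {method!r}")
    comp = ranking.competitors
    if not comp:
        comp = ranking.fits[:1]
    idx = [ranking.fits.index(f) for f in comp]
    w = ranking.weights[idx]
    w = w / w.sum()
    terms: list[str] = []
    for f in comp:
        for t in f.coefficients:
            if t not in terms:
                terms.append(t)
    averaged: dict[str, float] = {}
    for t in terms:
        betas = np.array([f.coefficients.get(t, 0.0) for f in comp])
        if method == "full":
            averaged[t] = float(np.sum(w * betas))
        else:
            has = np.array([t in f.coefficients for f in comp])
            averaged[t] = float(np.sum(w[has] * betas[has]) / w[has].sum())
    return averaged


def fit_all_subsets(
    table: pd.DataFrame,
    covariates: list[str] | None = None,
    response: str = "status",
    screen: bool = True,
) -> ModelRanking:
    """Convenience: screen, enumerate, fit and rank in one call."""
    covs = list(covariates) if covariates is not None else [
        c for c in table.columns if c != response
    ]
    if screen and len(covs) >= 2:
        covs = collinearity_screen(table, covs)
    fits = [fit_logistic(table, terms, response) for terms in enumerate_models(covs)]
    return rank_and_weight(fits)
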