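"""Logistic regression of metapopulation structure on larval duration.

Models the probability that a species' data select a stepping-stone
metapopulation model (coded 1; effective panmixia 0) as a function of
its maximum pelagic larval duration (PLD, days) and, optionally, the
great-circle distances from the focal site to the nearest and furthest
sampled populations.  Backward BIC selection prunes uninformative
terms.  The PLD coefficient is reported as the per-day percentage
change in the odds of stepping-stone structure,
``100 × (1 − exp(β_PLD))``, with Wald 95% intervals
(``β ± 1.96 × SE``) transformed the same way.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

from stepstone.errors import (
    ConfigurationError,
    DegenerateResponseError,
    DomainError,
)

EARTH_RADIUS_KM = 6371.0
_SEPARATION_COEF_LIMIT = 30.0


def great_circle_km(a: tuple[float, float], b: tuple[float, float]) -> float:
    """Haversine great-circle distance between (lat, lon) points in km."""
    for lat, lon in (a, b):
        if not (-90 <= lat <= 90 and -180 <= lon <= 180):
            raise DomainError(f"coordinates out of range: ({lat}, {lon})")
    lat1, lon1, lat2, lon2 = map(np.radians, (*a, *b))
    dlat = lat2 - lat1
    dlon = lon2 - lon1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return float(2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h)))


@dataclass
class RegressionResult:
    """A fitted logistic model and its reporting transforms."""

    terms: list[str]
    params: dict[str, float]
    bse: dict[str, float]
    llf: float
    bic: float
    n: int
    separated: bool = False
    bic_trace: list[tuple[tuple[str, ...], float]] = field(default_factory=list)

    def odds_change_percent(self, term: str = "pld") -> float:
        """Per-unit percentage decrease in odds, ``100 (1 - exp(β))``."""
        return 100.0 * (1.0 - np.exp(self.params[term]))

    def odds_change_ci95(self, term: str = "pld") -> tuple[float, float]:
        """Wald 95% CI on the odds-change-percent scale (lo, hi)."""
        beta = self.params[term]
        se = self.bse[term]
        lo_beta, hi_beta = beta - 1.96 * se, beta + 1.96 * se
        # 100(1-exp(b)) is decreasing in b, so the interval flips
        return (100.0 * (1.0 - np.exp(hi_beta)), 100.0 * (1.0 - np.exp(lo_beta)))

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        eta = np.full(len(X), self.params.get("const", 0.0))
        for term in self.terms:
            if term != "const":
                eta = eta + self.params[term] * X[term].to_numpy(dtype=float)
        return 1.0 / (1.0 + np.exp(-eta))


def _design(X: pd.DataFrame, terms: list[str]) -> pd.DataFrame:
    d = X[terms].astype(float).copy()
    d.insert(0, "const", 1.0)
    return d


def fit_logistic(y, X: pd.DataFrame, terms: list[str] | None = None) -> RegressionResult:
    """Maximum-likelihood logistic fit with IRLS.

    ``X`` is a DataFrame of covariates (an intercept is always added).
    Standard errors come from the inverse observed information.
    Complete separation is detected from divergent coefficients and
    flagged on the result rather than raised.
    """
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ConfigurationError("response must be binary 0/1")
    if len(np.unique(y)) < 2:
        raise DegenerateResponseError("response has a single class")
    terms = list(terms if terms is not None else X.columns)
    design = _design(X, terms)
    if len(y) < design.shape[1] + 1:
        raise ConfigurationError("need n >= number of parameters + 1")
    with warnings.catch_warnings(), np.errstate(all="ignore"):
        warnings.simplefilter("ignore")
        model = sm.GLM(y, design, family=sm.families.Binomial())
        fit = model.fit(maxiter=100, tol=1e-10)
        params = dict(zip(design.columns, fit.params))
        bse = dict(zip(design.columns, fit.bse))
        k = design.shape[1]
        n = len(y)
        bic = -2.0 * fit.llf + k * np.log(n)
    separated = bool(
        max(abs(v) for v in params.values()) > _SEPARATION_COEF_LIMIT
        or max(bse.values()) > 1e3
        or not np.all(np.isfinite(list(bse.values())))
    )
    return RegressionResult(
        terms=list(design.columns),
        params=params,
        bse=bse,
        llf=float(fit.llf),
        bic=float(bic),
        n=n,
        separated=separated,
    )


def backward_bic(y, X: pd.DataFrame, terms: list[str] | None = None) -> RegressionResult:
    """Backward elimination by BIC from the full covariate set.

    At each step the term whose removal most decreases BIC is dropped;
    elimination stops when no removal lowers BIC.  The intercept is
    never dropped.  The result carries the full BIC trace.
    """
    terms = list(terms if terms is not None else X.columns)

    def effective_bic(fit: RegressionResult) -> float:
        # a separated fit has a degenerate likelihood; its BIC cannot be
        # compared, so it is never allowed to win the elimination
        if fit.separated or not np.isfinite(fit.bic):
            return np.inf
        return fit.bic

    current = list(terms)
    best = fit_logistic(y, X, current)
    trace = [(tuple(best.terms), best.bic)]
    improved = True
    while improved and current:
        improved = False
        candidates = []
        for i, term in enumerate(current):
            reduced = [t for t in current if t != term]
            fit = fit_logistic(y, X, reduced) if reduced else _intercept_only(y)
            candidates.append((effective_bic(fit), i, term, fit))
        candidates.sort(key=lambda c: (c[0], c[1]))
        best_eff = effective_bic(best)
        # drop when the removal lowers BIC, or when the current model is
        # itself inadmissible (separated) and dropping makes progress
        if candidates[0][0] < best_eff or not np.isfinite(best_eff):
            _, _, dropped, best = candidates[0]
            current.remove(dropped)
            trace.append((tuple(best.terms), best.bic))
            improved = True
    best.bic_trace = trace
    return best


def _intercept_only(y) -> RegressionResult:
    y = np.asarray(y, dtype=float)
    n = len(y)
    p = y.mean()
    llf = float(np.sum(y * np.log(p) + (1 - y) * np.log1p(-p)))
    beta0 = float(np.log(p / (1 - p)))
    se = float(np.sqrt(1.0 / (n * p * (1 - p))))
    return RegressionResult(
        terms=["const"],
        params={"const": beta0},
        bse={"const": se},
        llf=llf,
        bic=float(-2 * llf + np.log(n)),
        n=n,
    )


def fitted_curve(
    result: RegressionResult, pld_grid=None
) -> pd.DataFrame:
    """Fitted stepping-stone probability over a PLD grid (20–70 days).

    Returns the point estimate together with the Wald 95% band
    (1.96 × SE on the linear predictor).
    """
    if pld_grid is None:
        pld_grid = np.arange(20.0, 70.5, 0.5)
    pld_grid = np.asarray(pld_grid, dtype=float)
    if "pld" not in result.params:
        raise ConfigurationError("fitted model does not retain a PLD term")
    eta = result.params["const"] + result.params["pld"] * pld_grid
    # band from per-coefficient Wald SEs (covariance term omitted)
    se_b0 = result.bse["const"]
    se_b1 = result.bse["pld"]
    se_eta = np.sqrt(se_b0**2 + (pld_grid * se_b1) ** 2)
    lo = 1 / (1 + np.exp(-(eta - 1.96 * se_eta)))
    hi = 1 / (1 + np.exp(-(eta + 1.96 * se_eta)))
    return pd.DataFrame(
        {
            "pld_days": pld_grid,
            "p_stepping_stone": 1 / (1 + np.exp(-eta)),
            "ci_low": lo,
            "ci_high": hi,
        }
    )
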