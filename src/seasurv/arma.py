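"""Seasonal vs non-seasonal ARMA model comparison under AIC.

Every combination of non-seasonal orders (p, q) up to 2 and seasonal orders
(P, Q) up to 2 at period 12 is fit by maximum likelihood with a constant
term; the class of a candidate is "seasonal" iff P + Q >= 1. The best
(lowest-AIC) converged model of each class is compared through the Akaike
evidence ratio RL = exp((AIC_nonseasonal - AIC_seasonal) / 2), and the site
is placed in one of five categories:

    RL > 5          SS   strongly seasonal
    2 < RL <= 5     S    seasonal
    1/2 <= RL <= 2  I    indeterminate
    1/5 <= RL < 1/2 N    non-seasonal
    RL < 1/5        NN   strongly non-seasonal

Boundary values resolve toward the weaker claim.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import product

import numpy as np
from statsmodels.tsa.arima.model import ARIMA

__all__ = [
    "ArmaFit",
    "ArmaVerdict",
    "candidate_orders",
    "fit_candidates",
    "best_fits",
    "classify",
    "arma_verdict",
]

CATEGORIES = ("SS", "S", "I", "N", "NN")


@dataclass(frozen=True)
class ArmaFit:
    p: int
    q: int
    P: int  # seasonal AR order at period 12
    Q: int  # seasonal MA order at period 12
    aic: float
    converged: bool

    @property
    def seasonal(self) -> bool:
        return self.P + self.Q >= 1

    @property
    def orders(self) -> tuple[int, int, int, int]:
        return (self.p, self.q, self.P, self.Q)


@dataclass(frozen=True)
class ArmaVerdict:
    category: str  # one of CATEGORIES
    relative_likelihood: float  # RL = exp((aic_n - aic_s)/2), > 0
    best_seasonal: ArmaFit | None
    best_nonseasonal: ArmaFit | None


def candidate_orders(max_order: int = 2, max_seasonal: int = 2) -> list[tuple[int, int, int, int]]:
    """All (p, q, P, Q) combinations on the grid."""
    r = range(max_order + 1)
    rs = range(max_seasonal + 1)
    return [(p, q, P, Q) for p, q, P, Q in product(r, r, rs, rs)]


def fit_candidates(
    values,
    max_order: int = 2,
    max_seasonal: int = 2,
    period: int = 12,
    maxiter: int = 100,
) -> list[ArmaFit]:
    """Fit the full candidate grid on a preprocessed (detrended) series.

    Candidates that fail to converge (or raise) are returned with
    ``converged=False`` and are excluded from selection, never silently
    treated as infinite AIC.
    """
    x = np.asarray(values, dtype=float)
    if x.ndim != 1 or x.size < 3 * period:
        raise ValueError(
            f"need >= {3 * period} months to identify period-{period} terms"
        )
    fits: list[ArmaFit] = []
    for p, q, P, Q in candidate_orders(max_order, max_seasonal):
        aic, converged = math.nan, False
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                model = ARIMA(
                    x,
                    order=(p, 0, q),
                    seasonal_order=(P, 0, Q, period),
                    trend="c",
                )
                res = model.fit(method_kwargs={"maxiter": maxiter})
            converged = bool(getattr(res, "mle_retvals", {}).get("converged", True))
            aic = float(res.aic)
            if not math.isfinite(aic):
                converged = False
        except Exception:
            pass
        fits.append(ArmaFit(p=p, q=q, P=P, Q=Q, aic=aic, converged=converged))
    return fits


def best_fits(fits) -> tuple[ArmaFit, ArmaFit]:
    """Lowest-AIC converged fit of each class (seasonal, non-seasonal)."""
    seasonal = [f for f in fits if f.converged and f.seasonal]
    nonseasonal = [f for f in fits if f.converged and not f.seasonal]
    if not seasonal:
        raise RuntimeError("class unfit: no seasonal candidate converged")
    if not nonseasonal:
        raise RuntimeError("class unfit: no non-seasonal candidate converged")
    key = lambda f: f.aic
    return min(seasonal, key=key), min(nonseasonal, key=key)


def classify(best_seasonal_aic: float, best_nonseasonal_aic: float) -> ArmaVerdict:
    """Five-tier category from the two best AICs (difference only matters)."""
    if not (math.isfinite(best_seasonal_aic) and math.isfinite(best_nonseasonal_aic)):
        raise ValueError("both AIC values must be finite")
    d = (best_nonseasonal_aic - best_seasonal_aic) / 2.0  # log evidence ratio
    rl = math.exp(min(max(d, -700.0), 700.0))  # clamp: huge |d| would over/underflow
    tol = 1e-9  # boundary values resolve toward the weaker claim
    ln5, ln2 = math.log(5.0), math.log(2.0)
    if d > ln5 + tol:
        cat = "SS"
    elif d > ln2 + tol:
        cat = "S"
    elif d >= -ln2 - tol:
        cat = "I"
    elif d >= -ln5 - tol:
        cat = "N"
    else:
        cat = "NN"
    return ArmaVerdict(
        category=cat, relative_likelihood=rl, best_seasonal=None, best_nonseasonal=None
    )


def arma_verdict(values, max_order: int = 2, max_seasonal: int = 2, period: int = 12) -> ArmaVerdict:
    """Full pipeline: fit the grid, select per class, classify."""
    fits = fit_candidates(values, max_order=max_order, max_seasonal=max_seasonal, period=period)
    best_s, best_n = best_fits(fits)
    verdict = classify(best_s.aic, best_n.aic)
    return ArmaVerdict(
        category=verdict.category,
        relative_likelihood=verdict.relative_likelihood,
        best_seasonal=best_s,
        best_nonseasonal=best_n,
    )
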