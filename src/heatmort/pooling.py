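"""Random-effects pooling of city-specific log relative risks (REML).

Model: observed city log-RRs y_i ~ Normal(mu, se_i^2 + tau^2), with the
between-city heterogeneity variance tau^2 estimated by restricted maximum
likelihood.  The pooled estimate is the inverse-variance weighted mean with
weights 1/(se_i^2 + tau^2), with a Wald 95% CI (no small-sample
adjustment), back-transformed to percent change per degC.

REML is solved by Fisher scoring on tau^2 with the estimate floored at
zero, falling back to bounded scalar minimisation of the negative
restricted log-likelihood if scoring fails to converge.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize_scalar

from .errors import EstimationError, InputError

Z975 = 1.959964


@dataclass
class PooledRisk:
    """REML random-effects pooled log relative risk."""

    pooled_beta: float
    pooled_se: float
    tau2: float
    n_cities: int
    estimates_in: list[tuple[str, float, float]] = field(default_factory=list)

    @property
    def pooled_pct_change(self) -> float:
        return (math.exp(self.pooled_beta) - 1.0) * 100.0

    @property
    def ci95(self) -> tuple[float, float]:
        lo = math.exp(self.pooled_beta - Z975 * self.pooled_se) - 1.0
        hi = math.exp(self.pooled_beta + Z975 * self.pooled_se) - 1.0
        return (lo * 100.0, hi * 100.0)

    @property
    def beta_ci95(self) -> tuple[float, float]:
        return (
            self.pooled_beta - Z975 * self.pooled_se,
            self.pooled_beta + Z975 * self.pooled_se,
        )

    def to_dict(self) -> dict:
        lo, hi = self.ci95
        return {
            "pooled_beta": self.pooled_beta,
            "pooled_se": self.pooled_se,
            "tau2": self.tau2,
            "n_cities": self.n_cities,
            "pooled_pct_change": self.pooled_pct_change,
            "ci_low": lo,
            "ci_high": hi,
        }


def se_from_ci(pct_low: float, pct_high: float) -> float:
    """Standard error of the log-RR from a percent-change 95% CI.

    Inverts the Wald interval: se = [ln(1 + hi/100) - ln(1 + lo/100)] / (2 z),
    z = 1.959964.  Percent bounds must satisfy -100 < lo < hi.
    """
    if pct_low <= -100 or pct_high <= -100:
        raise InputError("percent bounds must exceed -100")
    if not pct_low < pct_high:
        raise InputError(f"CI bounds out of order: ({pct_low}, {pct_high})")
    return (math.log1p(pct_high / 100.0) - math.log1p(pct_low / 100.0)) / (2 * Z975)


def restricted_loglik(tau2: float, betas: np.ndarray, variances: np.ndarray) -> float:
    """Restricted log-likelihood of the random-effects model at tau^2."""
    w = 1.0 / (variances + tau2)
    mu = np.sum(w * betas) / np.sum(w)
    return -0.5 * (
        np.sum(np.log(variances + tau2))
        + math.log(np.sum(w))
        + np.sum(w * (betas - mu) ** 2)
    )


def _reml_scoring(
    y: np.ndarray, v: np.ndarray, tol: float = 1e-10, max_iter: int = 100
) -> float | None:
    """Fisher scoring for tau^2, floored at 0; None if it does not settle."""
    tau2 = max(np.var(y, ddof=1) - v.mean(), 0.0)
    floored = 0
    for _ in range(max_iter):
        w = 1.0 / (v + tau2)
        sw, sw2, sw3 = np.sum(w), np.sum(w**2), np.sum(w**3)
        mu = np.sum(w * y) / sw
        resid2 = (y - mu) ** 2
        score = 0.5 * (np.sum(w**2 * resid2) - sw + sw2 / sw)
        info = 0.5 * (sw2 - 2 * sw3 / sw + (sw2 / sw) ** 2)
        if info <= 0:
            return None
        new = tau2 + score / info
        if new < 0:
            new = 0.0
            floored += 1
            if floored >= 2:
                return 0.0
        if abs(new - tau2) < tol:
            return float(new)
        tau2 = new
    return None


def pool_reml(
    estimates: list[tuple[float, float]] | list[tuple[str, float, float]],
    tol: float = 1e-10,
) -> PooledRisk:
    """REML random-effects pooling of (beta, se) pairs.

    ``estimates`` is a list of (beta, se) or (label, beta, se) tuples; at
    least two are required and all standard errors must be positive.
    """
    labelled: list[tuple[str, float, float]] = []
    for i, e in enumerate(estimates):
        if len(e) == 3:
            labelled.append((str(e[0]), float(e[1]), float(e[2])))
        else:
            labelled.append((f"estimate_{i}", float(e[0]), float(e[1])))
    if len(labelled) < 2:
        raise InputError("need >= 2 estimates to pool")
    y = np.array([b for _, b, _ in labelled])
    se = np.array([s for _, _, s in labelled])
    if (se <= 0).any():
        raise InputError("all standard errors must be > 0")
    v = se**2

    tau2 = _reml_scoring(y, v, tol=tol)
    if tau2 is None:
        upper = 10.0 * v.max() + np.var(y, ddof=1)
        res = minimize_scalar(
            lambda t2: -restricted_loglik(t2, y, v),
            bounds=(0.0, upper),
            method="bounded",
            options={"xatol": tol},
        )
        if not res.success:
            raise EstimationError("REML estimation of tau^2 did not converge")
        tau2 = float(res.x)
        if tau2 < tol:  # boundary solution
            tau2 = max(tau2, 0.0)

    w = 1.0 / (v + tau2)
    mu = float(np.sum(w * y) / np.sum(w))
    pooled_se = float(np.sum(w) ** -0.5)
    return PooledRisk(
        pooled_beta=mu,
        pooled_se=pooled_se,
        tau2=float(tau2),
        n_cities=len(labelled),
        estimates_in=labelled,
    )


def pool_published(rows: list[tuple[str, float, float, float]]) -> PooledRisk:
    """Pool published (city, pct_change, ci_low, ci_high) rows.

    Converts each row to log-RR and SE (via :func:`se_from_ci`) and applies
    :func:`pool_reml`.  This is how pooled estimates are recomputed from a
    table of published per-city percent changes.
    """
    est = [
        (city, math.log1p(pct / 100.0), se_from_ci(lo, hi))
        for city, pct, lo, hi in rows
    ]
    return pool_reml(est)
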