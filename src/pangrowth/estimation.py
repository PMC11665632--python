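"""Extrapolating pangenome growth and core size beyond the observed groups.

Three estimators, offered side by side without model selection:

* a Heaps'-law power fit to the growth increments, Δ(m) = κ·m^(−α) — the
  standard open/closed-pangenome diagnostic (α <= 1: open; α > 1: closed);
* an exponential decay fit to the core curve, F(m) = κ_c·exp(−m/τ_c) + Ω,
  whose offset Ω is the predicted asymptotic core size;
* the nonparametric Chao2 incidence-based richness estimator built from the
  singleton and doubleton counts of the coverage histogram.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Optional

import numpy as np
from scipy import optimize, stats

from .abacus import CoverageHistogram
from .curves import GrowthCurve

log = logging.getLogger(__name__)

__all__ = ["FitResult", "fit_power_law", "fit_exp_decay", "chao2"]


@dataclass
class FitResult:
    """Outcome of one extrapolation fit.

    ``predict`` maps a subset size m to the fitted/extrapolated curve value
    (absent for Chao2, which yields a single richness estimate in
    ``parameters``). ``rss`` is the residual sum of squares on the fitted
    range, in the space the fit was performed in.
    """

    model: str
    parameters: dict[str, float]
    predict: Optional[Callable[[float], float]] = None
    rss: float = float("nan")


class FitError(RuntimeError):
    """A fit could not be carried out (too few points, no convergence)."""


def fit_power_law(curve: GrowthCurve) -> FitResult:
    """Fit Δ(m) = κ·m^(−α) to the growth increments by log-log regression.

    The increments Δ(m) = value(m) − value(m−1), m = 2..n, are the
    new-countables-per-added-genome series; the fit is an ordinary linear
    regression of log Δ on log m (convex and deterministic). Non-positive
    increments cannot enter the log fit and are dropped with a warning.

    The extrapolant continues the observed curve:
    F(M) = value(n) + Σ_{m=n+1}^{M} κ·m^(−α). The verdict ``openness`` is
    "open" for α <= 1 (divergent Heaps sum) and "closed" otherwise.
    """
    n = curve.n
    if n < 3:
        raise FitError("power-law fit needs a curve with n >= 3")
    m = np.arange(2, n + 1)
    inc = np.diff(curve.values)
    usable = inc > 0
    if (~usable).any():
        log.warning(
            "power-law fit: dropped %d non-positive increment(s)",
            int((~usable).sum()),
        )
    m, inc = m[usable], inc[usable]
    if len(m) < 2:
        raise FitError("fewer than 2 positive increments; cannot fit")
    res = stats.linregress(np.log(m), np.log(inc))
    alpha = -res.slope
    kappa = float(np.exp(res.intercept))
    resid = np.log(inc) - (res.intercept + res.slope * np.log(m))
    rss = float(np.sum(resid**2))
    vn = curve.value_at(n)

    def predict(M: float) -> float:
        M = int(M)
        if M <= n:
            return curve.value_at(max(M, 1))
        extra = kappa * np.power(np.arange(n + 1, M + 1, dtype=float), -alpha)
        return float(vn + extra.sum())

    return FitResult(
        model="power_law",
        parameters={
            "kappa": kappa,
            "alpha": float(alpha),
            "openness": 1.0 if alpha <= 1 else 0.0,
        },
        predict=predict,
        rss=rss,
    )


def _exp_model(m: np.ndarray, kappa: float, tau: float, omega: float
               ) -> np.ndarray:
    return kappa * np.exp(-m / tau) + omega


def fit_exp_decay(core: GrowthCurve) -> FitResult:
    """Fit F(m) = κ_c·exp(−m/τ_c) + Ω to a strict core curve.

    Ω is the predicted asymptotic core size. Initialization (Ω₀ = min,
    κ₀ = max − min, τ₀ = n/4) and bounds (κ, Ω >= 0, τ > 0) are chosen for
    robust convergence on monotone decreasing data.
    """
    n = core.n
    if n < 4:
        raise FitError("exponential-decay fit needs a curve with n >= 4")
    m = np.arange(1, n + 1, dtype=float)
    y = core.values.astype(float)
    ymin, ymax = float(y.min()), float(y.max())
    p0 = [max(ymax - ymin, 1e-9), max(n / 4.0, 1e-6), max(ymin, 0.0)]
    try:
        popt, _ = optimize.curve_fit(
            _exp_model, m, y, p0=p0,
            bounds=([0.0, 1e-9, 0.0], [np.inf, np.inf, np.inf]),
            maxfev=20000,
        )
    except RuntimeError as exc:  # no convergence
        raise FitError(f"exponential-decay fit did not converge: {exc}")
    kappa, tau, omega = (float(v) for v in popt)
    rss = float(np.sum((y - _exp_model(m, kappa, tau, omega)) ** 2))

    def predict(M: float) -> float:
        return float(_exp_model(np.asarray(float(M)), kappa, tau, omega))

    return FitResult(
        model="exp_decay",
        parameters={"kappa_c": kappa, "tau_c": tau, "omega": omega},
        predict=predict,
        rss=rss,
    )


def chao2(hist: CoverageHistogram) -> FitResult:
    """Chao2 incidence-based richness estimate from h(1) and h(2).

    With S_obs = Σ_{i>=1} h(i), q1 = h(1) (countables seen in exactly one
    group) and q2 = h(2): the classic estimate is S_obs + q1²/(2·q2); when
    no doubletons exist the bias-corrected S_obs + q1·(q1−1)/2 is used. The
    bias-corrected variant S_obs + ((n−1)/n)·q1·(q1−1)/(2·(q2+1)) is always
    reported alongside. The estimate never falls below S_obs.
    """
    if hist.n < 2:
        raise ValueError("Chao2 requires at least two groups")
    s_obs = hist.total_covered
    if s_obs == 0:
        raise ValueError("empty histogram: nothing observed")
    q1, q2 = float(hist.h[1]), float(hist.h[2])
    if q2 > 0:
        estimate = s_obs + q1 * q1 / (2.0 * q2)
    else:
        estimate = s_obs + q1 * (q1 - 1.0) / 2.0
    n = hist.n
    bias_corrected = s_obs + (n - 1.0) / n * q1 * (q1 - 1.0) / (2.0 * (q2 + 1.0))
    return FitResult(
        model="chao2",
        parameters={
            "S_obs": s_obs,
            "q1": q1,
            "q2": q2,
            "estimate": estimate,
            "estimate_bias_corrected": bias_corrected,
        },
    )
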