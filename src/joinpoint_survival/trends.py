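"""Trend measures on the hazard and survival scales, with delta-method CIs.

Two summaries of how prognosis changes with calendar year of diagnosis:

``APC_D``
    annual percent change in the conditional (interval) probability of
    cancer death, ``100 * (exp(beta*) - 1)`` with ``beta*`` the segment
    slope on the log-hazard scale.  A relative measure; constant within a
    segment and identical across follow-up intervals.

``AAC_S(t)``
    average annual absolute change of cumulative t-year survival across the
    diagnosis years of a segment, in percentage points.  The average of the
    consecutive-year differences telescopes exactly to
    ``100 * [S(t | end) - S(t | start)] / (end - start)``.

The two move in opposite directions: when survival improves (AAC_S > 0) the
annual probability of death falls (APC_D < 0).

Standard errors treat the joinpoint locations as fixed and propagate the
coefficient covariance: analytically through the closed form
``S(t|x) = S0(t) ** exp(h(x))``, with a central finite-difference fallback
used to cross-validate the analytic gradient.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .lifetable import ObservedSurvival
from .model import (
    FitResult,
    ModelParams,
    conditional_death_prob,
    hazard_offset,
    predict_cumulative_survival,
)

__all__ = [
    "TrendEstimate",
    "segment_slope",
    "apc_d",
    "aac_s",
    "trend_table",
    "project_survival",
    "plot_survival_by_year",
    "plot_death_prob_by_year",
    "plot_survival_curves",
    "percent_change",
    "absolute_change_pp",
    "cumulative_change",
    "relative_risk_from_apc",
    "apc_from_relative_risk",
]

Z95 = 1.959963984540054  # two-sided 95% normal quantile


@dataclass(frozen=True)
class TrendEstimate:
    """A segment trend measure with its delta-method 95% CI.

    ``direction`` follows the sign of a significant estimate (``"up"`` /
    ``"down"``) and is ``"ns"`` when the CI spans zero.  ``estimate`` is in
    percent for ``apc_d`` and percentage points for ``aac_s``.
    """

    measure: str                      # "apc_d" | "aac_s"
    segment: tuple[int, int]          # [start_year, end_year]
    estimate: float
    se: float
    t: int | None = None              # follow-up years; aac_s only

    @property
    def ci95(self) -> tuple[float, float]:
        return (self.estimate - Z95 * self.se, self.estimate + Z95 * self.se)

    @property
    def significant(self) -> bool:
        lo, hi = self.ci95
        return lo > 0.0 or hi < 0.0

    @property
    def direction(self) -> str:
        if not self.significant:
            return "ns"
        return "up" if self.estimate > 0 else "down"


def _slope_contrast(params: ModelParams, m: int) -> np.ndarray:
    """0/1 vector c with c' theta = beta + sum_{k<=m} delta_k."""
    J, K = params.n_intervals, params.n_joinpoints
    if not 0 <= m <= K:
        raise ValueError(f"segment index {m} out of range 0..{K}")
    c = np.zeros(J + 1 + K)
    c[J] = 1.0
    c[J + 1: J + 1 + m] = 1.0
    return c


def segment_slope(fit: FitResult, m: int) -> tuple[float, float]:
    """Slope ``beta* = beta + sum_{k<=m} delta_k`` of segment ``m`` and its SE."""
    c = _slope_contrast(fit.params, m)
    beta_star = fit.params.segment_slope(m)
    se = float(np.sqrt(c @ fit.cov @ c))
    return beta_star, se


def apc_d(fit: FitResult, segment_index: int) -> TrendEstimate:
    """Annual percent change in the probability of cancer death for a segment.

    ``APC_D = 100 * (exp(beta*) - 1)``; a value of -2 means the conditional
    probability of dying of cancer falls 2% per later year of diagnosis,
    i.e. a 0.98 year-over-year relative risk.  SE by the delta method:
    ``100 * exp(beta*) * se(beta*)``.
    """
    beta_star, se_b = segment_slope(fit, segment_index)
    est = 100.0 * (np.exp(beta_star) - 1.0)
    se = 100.0 * np.exp(beta_star) * se_b
    seg = fit.params.segment_bounds(*fit.year_range)[segment_index]
    return TrendEstimate("apc_d", seg, float(est), float(se))


def _survival_gradient(params: ModelParams, x: float, t: int) -> tuple[float, np.ndarray]:
    """S(t|x) and its gradient w.r.t. the free coefficients (alphas, beta, deltas)."""
    J, K = params.n_intervals, params.n_joinpoints
    lam = np.exp(params.alphas)
    lam0 = float(lam[:t].sum())
    E = float(np.exp(hazard_offset(x, params)))
    S = float(np.exp(-lam0 * E))
    g = np.zeros(J + 1 + K)
    g[:t] = -S * E * lam[:t]
    g[J] = -S * lam0 * E * (x - params.year_anchor)
    for k in range(K):
        g[J + 1 + k] = -S * lam0 * E * max(x - params.taus[k], 0.0)
    return S, g


def _fd_survival_gradient(params: ModelParams, x: float, t: int,
                          rel_step: float = 1e-6) -> np.ndarray:
    """Central finite-difference gradient of S(t|x); cross-check for the analytic form."""
    J, K = params.n_intervals, params.n_joinpoints
    theta = np.concatenate([params.alphas, [params.beta], params.deltas])
    g = np.zeros_like(theta)
    for i in range(len(theta)):
        h = rel_step * max(1.0, abs(theta[i]))
        for sign in (+1, -1):
            th = theta.copy()
            th[i] += sign * h
            p = ModelParams(th[:J], float(th[J]), th[J + 1:], params.taus,
                            params.year_anchor)
            g[i] += sign * predict_cumulative_survival(p, x, t)
        g[i] /= 2 * h
    return g


def aac_s(
    fit: FitResult,
    t: int,
    year_start: int,
    year_end: int,
    gradient: str = "analytic",
) -> TrendEstimate:
    """Average annual absolute change in t-year survival over [start, end].

    Averaging ``100 * [S(t|x+1) - S(t|x)]`` over consecutive years in the
    window telescopes to ``100 * [S(t|end) - S(t|start)] / (end - start)``,
    which is what is computed; the SE propagates the telescoped expression's
    gradient through the coefficient covariance.
    """
    if year_end <= year_start:
        raise ValueError("year_end must exceed year_start (no single-year segments)")
    if not 1 <= t <= fit.params.n_intervals:
        raise ValueError(
            f"t={t} outside available follow-up 1..{fit.params.n_intervals}"
        )
    span = year_end - year_start
    S1, g1 = _survival_gradient(fit.params, year_end, t)
    S0, g0 = _survival_gradient(fit.params, year_start, t)
    if gradient == "fd":
        g1 = _fd_survival_gradient(fit.params, year_end, t)
        g0 = _fd_survival_gradient(fit.params, year_start, t)
    elif gradient != "analytic":
        raise ValueError("gradient must be 'analytic' or 'fd'")
    est = 100.0 * (S1 - S0) / span
    g = 100.0 * (g1 - g0) / span
    se = float(np.sqrt(g @ fit.cov @ g))
    return TrendEstimate("aac_s", (int(year_start), int(year_end)), float(est),
                         se, t=int(t))


def aac_s_averaged(fit: FitResult, t: int, year_start: int, year_end: int) -> float:
    """AAC_S(t) by explicit averaging of consecutive-year differences.

    Algebraically identical to the telescoped form in :func:`aac_s`; kept as
    the direct transcription of the definition.
    """
    years = np.arange(year_start, year_end)
    diffs = [
        predict_cumulative_survival(fit.params, x + 1, t)
        - predict_cumulative_survival(fit.params, x, t)
        for x in years
    ]
    return float(100.0 * np.mean(diffs))


def trend_table(
    fit: FitResult,
    t_values: Sequence[int] = (5, 1),
    highlight_aac: float = 1.0,
    highlight_apc: float = -5.0,
) -> pd.DataFrame:
    """Per-segment trend summary: AAC_S(t) for each requested t, plus APC_D.

    One row per (segment, measure); ``highlight`` marks the conventionally
    emphasised trends (AAC_S above ``highlight_aac`` percentage points, or
    APC_D below ``highlight_apc`` percent).
    """
    rows = []
    segments = fit.params.segment_bounds(*fit.year_range)
    for m, (start, end) in enumerate(segments):
        for t in t_values:
            est = aac_s(fit, t, start, end)
            rows.append(_trend_row(m, est, est.estimate > highlight_aac))
        est = apc_d(fit, m)
        rows.append(_trend_row(m, est, est.estimate < highlight_apc))
    return pd.DataFrame(rows)


def _trend_row(m: int, est: TrendEstimate, highlight: bool) -> dict:
    lo, hi = est.ci95
    return {
        "segment": m,
        "start_year": est.segment[0],
        "end_year": est.segment[1],
        "measure": est.measure if est.t is None else f"{est.measure}({est.t})",
        "estimate": est.estimate,
        "se": est.se,
        "ci_lo": lo,
        "ci_hi": hi,
        "direction": est.direction,
        "highlight": bool(highlight and est.significant),
    }


# ---------------------------------------------------------------------------
# projection and plotting surfaces

def project_survival(
    fit: FitResult,
    horizon: int = 0,
    t_values: Sequence[int] | None = None,
    observed: ObservedSurvival | None = None,
) -> pd.DataFrame:
    """Cumulative survival surface over observed years plus ``horizon`` more.

    Beyond the last data year the last segment's slope simply continues:
    ``h(x)`` is linear past the final joinpoint, so no special-casing is
    needed and the surface is continuous at the boundary.  Rows carry a
    ``projected`` flag, true for diagnosis years beyond the data or — when
    ``observed`` is supplied — for (year, t) cells with no observed
    follow-up (recent diagnosis years whose t-year survival is not yet
    observable).
    """
    if horizon < 0:
        raise ValueError("horizon must be >= 0")
    lo, hi = fit.year_range
    if t_values is None:
        t_values = list(range(1, fit.params.n_intervals + 1))
    years = np.arange(lo, hi + horizon + 1)
    seen: set[tuple[int, int]] = set()
    if observed is not None:
        seen = set(zip(observed.data["Year"].astype(int),
                       observed.data["Interval"].astype(int)))
    rows = []
    for x in years:
        for t in t_values:
            S = predict_cumulative_survival(fit.params, x, t)
            projected = x > hi or (observed is not None and (int(x), int(t)) not in seen)
            rows.append({"Year": int(x), "t": int(t), "S_model": S,
                         "projected": projected})
    return pd.DataFrame(rows)


def plot_survival_by_year(
    fit: FitResult,
    observed: ObservedSurvival | None,
    t_values: Sequence[int],
    horizon: int = 0,
) -> pd.DataFrame:
    """Dataset for the survival-by-diagnosis-year plot.

    One row per (year, t): modeled cumulative survival with a projection
    flag, and — where available — the observed life-table value with its
    Greenwood SE, passed through verbatim.
    """
    if not len(t_values):
        raise ValueError("t_values must be non-empty")
    surf = project_survival(fit, horizon=horizon, t_values=t_values,
                            observed=observed)
    if observed is None:
        surf["S_obs"] = np.nan
        surf["se_obs"] = np.nan
        return surf
    obs = observed.data.rename(columns={"Interval": "t"})
    obs = obs[["Year", "t", "S_obs_cum", "se_S"]].rename(
        columns={"S_obs_cum": "S_obs", "se_S": "se_obs"})
    return surf.merge(obs, on=["Year", "t"], how="left")


def plot_death_prob_by_year(
    fit: FitResult,
    observed: ObservedSurvival | None,
    j_values: Sequence[int],
    horizon: int = 0,
) -> pd.DataFrame:
    """Dataset for the annual-probability-of-death plot.

    One row per (year, interval j): modeled conditional death probability
    ``lambda_j(x)`` and the observed net value ``1 - r_obs_interval``.
    Systematic opposite-signed observed-minus-modeled residuals at early vs
    late j are the visual signature of a proportionality violation.
    """
    if not len(j_values):
        raise ValueError("j_values must be non-empty")
    lo, hi = fit.year_range
    years = np.arange(lo, hi + horizon + 1)
    rows = []
    for x in years:
        for j in j_values:
            rows.append({
                "Year": int(x), "j": int(j),
                "p_model": conditional_death_prob(fit.params, x, j),
                "projected": x > hi,
            })
    out = pd.DataFrame(rows)
    if observed is None:
        out["p_obs"] = np.nan
        return out
    obs = observed.data.rename(columns={"Interval": "j"})
    obs = obs.assign(p_obs=1.0 - obs["r_obs_interval"])[["Year", "j", "p_obs"]]
    return out.merge(obs, on=["Year", "j"], how="left")


def plot_survival_curves(fit: FitResult, years: Sequence[int]) -> pd.DataFrame:
    """Dataset of cumulative survival vs time since diagnosis, one curve per year."""
    rows = []
    for x in years:
        for t in range(1, fit.params.n_intervals + 1):
            rows.append({"Year": int(x), "t": t,
                         "S_model": predict_cumulative_survival(fit.params, x, t)})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# scale helpers (interpretation arithmetic)

def percent_change(p_from: float, p_to: float) -> float:
    """Relative change in percent: 40 -> 38 is a -5% change."""
    return 100.0 * (p_to - p_from) / p_from


def absolute_change_pp(s_from: float, s_to: float) -> float:
    """Difference of two percentages, in percentage points: 40 -> 42 is +2 pp."""
    return s_to - s_from


def cumulative_change(aac: float, n_years: int) -> float:
    """Total survival change implied by a sustained AAC_S over ``n_years``."""
    return aac * n_years


def relative_risk_from_apc(apc: float) -> float:
    """Year-over-year relative risk exp(beta*) implied by an APC_D in percent.

    Inverts ``APC_D = 100 * (exp(beta*) - 1)``: an APC_D of -2 corresponds
    to a 0.98 annual relative risk of cancer death.
    """
    from scipy.optimize import brentq

    beta_star = brentq(lambda b: 100.0 * (np.exp(b) - 1.0) - apc, -5.0, 5.0,
                       xtol=1e-14)
    return float(np.exp(beta_star))


def apc_from_relative_risk(rr: float) -> float:
    """APC_D in percent for a year-over-year relative risk ``rr = exp(beta*)``."""
    if rr <= 0:
        raise ValueError("relative risk must be positive")
    return 100.0 * (np.exp(np.log(rr)) - 1.0)
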