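"""Joinpoint proportional-hazards model for grouped survival data.

The hazard of cancer death at follow-up time ``t`` for patients diagnosed in
calendar year ``x`` is modelled as ``lambda_0(t) * exp(h(x))`` where the
calendar-year effect

    h(x) = beta * x + sum_k delta_k * (x - tau_k)+

is piecewise linear with joinpoints at years ``tau_1 < ... < tau_K`` and
``(u)+ = max(u, 0)``.  With no joinpoint the model is a Cox proportional
hazards model with diagnosis year as the single covariate.

Time is discrete (annual follow-up intervals).  The baseline hazard enters
as one log cumulative-hazard mass ``alpha_j`` per interval, so the net
(cancer-specific / relative) conditional survival of interval ``j`` is

    s_j(x) = exp(-exp(alpha_j + h(x)))

and cumulative net survival is ``S(t|x) = S_0(t) ** exp(h(x))`` with
``S_0(t) = exp(-sum_{j<=t} exp(alpha_j))``.

The likelihood is a grouped binomial on the observed death fractions with
the actuarial effective denominators as prior weights: the all-cause
interval death probability of a cell is ``pi = 1 - e * s_j(x)`` in relative
mode (``e`` the expected interval survival of the matched population) and
``pi = 1 - s_j(x)`` in cause-specific / overall mode.  Maximisation at fixed
joinpoints is Fisher-scoring IRLS with step-halving; the covariance of the
free coefficients ``(alpha_1..alpha_J, beta, delta_1..delta_K)`` is the
inverse observed information at the optimum (joinpoint locations are treated
as fixed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .lifetable import SurvivalTable

__all__ = [
    "ModelParams",
    "FitResult",
    "FitError",
    "hazard_offset",
    "predict_interval_survival",
    "predict_cumulative_survival",
    "conditional_death_prob",
    "log_likelihood",
    "fit_fixed_joinpoints",
    "information_criteria",
]

PROB_CLIP = 1e-12


class FitError(RuntimeError):
    """Degenerate design or invalid model dimensions."""


@dataclass(frozen=True)
class ModelParams:
    """Coefficients of a fitted (or generative) joinpoint survival model.

    Attributes
    ----------
    alphas
        Interval baseline log cumulative-hazard masses, one per follow-up
        interval ``j = 1..J``.
    beta
        Slope of the first segment, per year of diagnosis, on the log-hazard
        scale.
    deltas
        Slope changes at each joinpoint; the slope of segment ``m`` (after
        the ``m``-th joinpoint) is ``beta + sum_{k<=m} deltas[k]``.
    taus
        Joinpoint calendar years, strictly increasing; empty for K = 0.
    year_anchor
        Calendar year treated as ``x = 0`` for numerical conditioning.  The
        hinge terms use the raw calendar years, so predictions are invariant
        to the anchor once ``alphas``/``beta`` are expressed against it.
    """

    alphas: np.ndarray
    beta: float
    deltas: np.ndarray = field(default_factory=lambda: np.empty(0))
    taus: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    year_anchor: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "alphas", np.asarray(self.alphas, dtype=float))
        object.__setattr__(self, "deltas", np.asarray(self.deltas, dtype=float))
        object.__setattr__(self, "taus", np.asarray(self.taus, dtype=int))
        if len(self.deltas) != len(self.taus):
            raise FitError("deltas and taus must have equal length")
        if len(self.taus) > 1 and np.any(np.diff(self.taus) <= 0):
            raise FitError("taus must be strictly increasing")

    @property
    def n_intervals(self) -> int:
        return len(self.alphas)

    @property
    def n_joinpoints(self) -> int:
        return len(self.taus)

    def segment_slope(self, m: int) -> float:
        """Slope ``beta + sum_{k<=m} delta_k`` of segment ``m`` (0-based)."""
        if not 0 <= m <= self.n_joinpoints:
            raise FitError(f"segment index {m} out of range 0..{self.n_joinpoints}")
        return float(self.beta + self.deltas[:m].sum())

    def segment_bounds(self, year_min: int, year_max: int) -> list[tuple[int, int]]:
        """Segment year windows [start, end] implied by the joinpoints."""
        knots = [year_min, *self.taus.tolist(), year_max]
        return [(int(knots[m]), int(knots[m + 1])) for m in range(len(knots) - 1)]


@dataclass(frozen=True)
class FitResult:
    """A maximum-likelihood fit at fixed joinpoint locations.

    ``cov`` is over the free coefficients (alphas, beta, deltas) in that
    order; joinpoint years are not estimated parameters of the covariance
    but each contributes one unit to the parameter count ``p`` penalised by
    the information criteria (its location was searched).
    """

    params: ModelParams
    loglik: float
    cov: np.ndarray
    n_cells: int
    p: int
    bic: float
    aic: float
    converged: bool
    n_iter: int
    mode: str
    n_clipped: int = 0
    grad_norm: float = float("nan")
    year_range: tuple[int, int] = (0, 0)

    @property
    def n_joinpoints(self) -> int:
        return self.params.n_joinpoints


def hazard_offset(x, params: ModelParams):
    """Log-hazard offset ``h(x)`` relative to the anchored baseline.

    ``h(x) = beta * (x - anchor) + sum_k delta_k * (x - tau_k)+``.  Total in
    ``x`` (projection evaluates it beyond the data range); piecewise linear
    and continuous.  Accepts scalars or arrays.
    """
    x = np.asarray(x, dtype=float)
    h = params.beta * (x - params.year_anchor)
    for delta, tau in zip(params.deltas, params.taus):
        h = h + delta * np.maximum(x - tau, 0.0)
    return h if h.ndim else float(h)


def _check_interval(params: ModelParams, j) -> np.ndarray:
    j = np.asarray(j, dtype=int)
    if np.any(j < 1) or np.any(j > params.n_intervals):
        raise FitError(
            f"interval index out of range 1..{params.n_intervals}"
        )
    return j


def predict_interval_survival(params: ModelParams, x, j):
    """Net conditional survival ``s_j(x) = exp(-exp(alpha_j + h(x)))``."""
    j = _check_interval(params, j)
    eta = params.alphas[j - 1] + hazard_offset(x, params)
    s = np.exp(-np.exp(eta))
    return s if np.ndim(s) else float(s)

def predict_cumulative_survival(params: ModelParams, x, t):
    """Cumulative net survival ``S(t|x) = prod_{j<=t} s_j(x)``.

    Equals ``S_0(t) ** exp(h(x))`` exactly: the cumulative hazard is
    ``exp(h(x)) * sum_{j<=t} exp(alpha_j)``.
    """
    t = np.asarray(t, dtype=int)
    if np.any(t < 1) or np.any(t > params.n_intervals):
        raise FitError(f"follow-up time out of range 1..{params.n_intervals}")
    lam0 = np.cumsum(np.exp(params.alphas))  # baseline cumulative hazard
    S = np.exp(-lam0[t - 1] * np.exp(hazard_offset(x, params)))
    return S if np.ndim(S) else float(S)


def conditional_death_prob(params: ModelParams, x, j):
    """Conditional probability of cancer death in interval ``j``: ``1 - s_j(x)``."""
    s = predict_interval_survival(params, x, j)
    return 1.0 - s


def information_criteria(loglik: float, p: int, n_cells: int) -> tuple[float, float]:
    """(BIC, AIC) = (-2l + p log n, -2l + 2p); ``n`` counts (year, interval) cells."""
    return (-2.0 * loglik + p * np.log(n_cells), -2.0 * loglik + 2.0 * p)


# ---------------------------------------------------------------------------
# likelihood machinery

def _cells(table: SurvivalTable):
    """Extract per-cell arrays (x, j, n_eff, y, e) from a validated table."""
    df = table.data
    x = df["Year"].to_numpy(float)
    j = df["Interval"].to_numpy(int)
    n_eff = df["Alive_at_Start"].to_numpy(float) - df["Lost_to_Followup"].to_numpy(float) / 2.0
    y = np.where(n_eff > 0, df["Died"].to_numpy(float) / np.where(n_eff > 0, n_eff, 1.0), 0.0)
    if table.mode == "relative":
        e = df["Expected_Survival_Interval"].to_numpy(float)
    else:
        e = np.ones(len(df))
    return x, j, n_eff, y, e


def _design_matrix(x: np.ndarray, j: np.ndarray, J: int,
                   taus: np.ndarray, anchor: float) -> np.ndarray:
    """Columns: J interval indicators, centred year, K hinge terms."""
    n = len(x)
    K = len(taus)
    X = np.zeros((n, J + 1 + K))
    X[np.arange(n), j - 1] = 1.0
    X[:, J] = x - anchor
    for k, tau in enumerate(taus):
        X[:, J + 1 + k] = np.maximum(x - tau, 0.0)
    return X


def _loglik_terms(eta: np.ndarray, y: np.ndarray, w: np.ndarray, e: np.ndarray):
    """Per-cell log-likelihood pieces; returns (ll, pi, n_clipped)."""
    s = np.exp(-np.exp(np.clip(eta, -700.0, 700.0)))
    pi = 1.0 - e * s
    clipped = (pi < PROB_CLIP) | (pi > 1.0 - PROB_CLIP)
    pi = np.clip(pi, PROB_CLIP, 1.0 - PROB_CLIP)
    ll = float(np.sum(w * (y * np.log(pi) + (1.0 - y) * np.log1p(-pi))))
    return ll, pi, int(clipped.sum())


def log_likelihood(params: ModelParams, table: SurvivalTable) -> float:
    """Grouped (quasi-)binomial log-likelihood of the table under ``params``.

    Each (year, interval) cell contributes
    ``n_eff * [y log pi + (1 - y) log(1 - pi)]`` with ``y`` the observed
    death fraction and ``pi`` the fitted all-cause interval death
    probability.  Probabilities are clipped to ``[1e-12, 1 - 1e-12]``.
    """
    x, j, n_eff, y, e = _cells(table)
    if params.n_intervals < j.max():
        raise FitError(
            f"params have {params.n_intervals} intervals but table needs {j.max()}"
        )
    eta = params.alphas[j - 1] + hazard_offset(x, params)
    ll, _, _ = _loglik_terms(eta, y, n_eff, e)
    return ll


def _check_segments(years: np.ndarray, taus: np.ndarray) -> None:
    """Each joinpoint segment must contain at least two diagnosis years.

    Segments are half-open ``[knot, next knot)`` except the last, which is
    closed; a single-year segment leaves its slope effectively unidentified.
    """
    bounds = [years.min(), *taus.tolist(), years.max()]
    for m in range(len(bounds) - 1):
        lo, hi = bounds[m], bounds[m + 1]
        last = m == len(bounds) - 2
        inseg = (years >= lo) & ((years <= hi) if last else (years < hi))
        if inseg.sum() < 2:
            raise FitError(
                f"segment {m} ({lo}-{hi}) contains fewer than two diagnosis "
                "years; slope not identifiable"
            )


def fit_fixed_joinpoints(
    table: SurvivalTable,
    taus: Sequence[int] = (),
    max_iter: int = 100,
    tol: float = 1e-8,
    year_anchor: int | None = None,
) -> FitResult:
    """Maximise the likelihood over (alphas, beta, deltas) at fixed joinpoints.

    Fisher-scoring IRLS on the complementary-log-log grouped binomial model
    with the calendar-year offset structure of :func:`hazard_offset`,
    effective denominators as prior weights, and step-halving whenever a
    proposed step lowers the likelihood.  Convergence is a relative change
    in log-likelihood below ``tol``; non-convergence is reported via the
    ``converged`` flag, not an exception, so a grid search can skip the fit.
    """
    taus = np.asarray(sorted(int(t) for t in taus), dtype=int)
    x, j, n_eff, y, e = _cells(table)
    years = np.unique(x)
    if len(years) < 2:
        raise FitError("need at least two diagnosis years to fit a trend")
    lo, hi = int(years.min()), int(years.max())
    if len(taus) and (taus.min() <= lo or taus.max() >= hi):
        raise FitError("joinpoints must lie strictly inside the year range")
    _check_segments(years, taus)

    J = int(j.max())
    K = len(taus)
    anchor = lo if year_anchor is None else int(year_anchor)
    X = _design_matrix(x, j, J, taus, anchor)
    w = n_eff

    # initial values: pooled per-interval net survival, flat trend
    theta = np.zeros(J + 1 + K)
    for iv in range(1, J + 1):
        sel = j == iv
        s_net = (1.0 - y[sel]) / e[sel]
        s_bar = float(np.clip(np.average(s_net, weights=w[sel]), 1e-6, 1 - 1e-6))
        theta[iv - 1] = np.log(-np.log(s_bar))

    ll, _, _ = _loglik_terms(X @ theta, y, w, e)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # eta clipped against overflow; a cell pinned at a survival boundary
        # then contributes ~zero weight and the pseudo-inverse handles the
        # (numerically) flat direction
        eta = np.clip(X @ theta, -30.0, 30.0)
        u = np.exp(eta)
        s = np.exp(-u)
        pi = np.clip(1.0 - e * s, PROB_CLIP, 1.0 - PROB_CLIP)
        m = e * s * u                      # d pi / d eta
        v = pi * (1.0 - pi)
        score = X.T @ (w * (y - pi) / v * m)
        W = w * m * m / v                  # expected information weights
        XtWX = X.T @ (X * W[:, None])
        try:
            step = np.linalg.solve(XtWX, score)
            if not np.all(np.isfinite(step)):
                raise np.linalg.LinAlgError("non-finite step")
        except np.linalg.LinAlgError:
            step = np.linalg.pinv(XtWX) @ score

        # step-halving line search on the likelihood
        new_ll = -np.inf
        scale = 1.0
        for _ in range(30):
            cand = theta + scale * step
            new_ll, _, _ = _loglik_terms(X @ cand, y, w, e)
            if new_ll >= ll - 1e-14:
                break
            scale *= 0.5
        if new_ll < ll - 1e-10:   # could not improve at all
            break
        theta = theta + scale * step
        if abs(new_ll - ll) < tol * (abs(new_ll) + 1.0):
            ll = new_ll
            converged = True
            break
        ll = new_ll

    eta = np.clip(X @ theta, -30.0, 30.0)
    u = np.exp(eta)
    s = np.exp(-u)
    pi_raw = 1.0 - e * s
    pi = np.clip(pi_raw, PROB_CLIP, 1.0 - PROB_CLIP)
    n_clipped = int(((pi_raw < PROB_CLIP) | (pi_raw > 1 - PROB_CLIP)).sum())
    m = e * s * u
    v = pi * (1.0 - pi)
    resid = (y - pi) / v
    score = X.T @ (w * resid * m)

    # observed information: -d2 ll / d eta2, cell-wise, then X' D X
    dm = m * (1.0 - u)
    da = -m * (v + (y - pi) * (1.0 - 2.0 * pi)) / (v * v)
    d2 = w * (resid * dm + m * da)
    H = X.T @ (X * d2[:, None])
    try:
        cov = np.linalg.inv(-H)
    except np.linalg.LinAlgError:
        cov = np.full((len(theta), len(theta)), np.nan)
    # symmetrise against round-off
    cov = (cov + cov.T) / 2.0

    params = ModelParams(
        alphas=theta[:J],
        beta=float(theta[J]),
        deltas=theta[J + 1:],
        taus=taus,
        year_anchor=anchor,
    )
    p = J + 1 + 2 * K
    n_cells = len(x)
    bic, aic = information_criteria(ll, p, n_cells)
    return FitResult(
        params=params,
        loglik=ll,
        cov=cov,
        n_cells=n_cells,
        p=p,
        bic=float(bic),
        aic=float(aic),
        converged=converged,
        n_iter=it,
        mode=table.mode,
        n_clipped=n_clipped,
        grad_norm=float(np.linalg.norm(score) / (1.0 + abs(ll))),
        year_range=(lo, hi),
    )
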