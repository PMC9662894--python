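"""Scikit-learn-style estimator wrapping the full joinpoint survival pipeline.

``JoinpointSurvivalModel`` is the package's main entry point: ``fit`` takes a
grouped survival life table, runs the joinpoint grid search with IRLS at each
candidate, selects the number of joinpoints by BIC (or AIC), and exposes the
fitted model through predict-style methods and trend summaries.  It follows
the scikit-learn estimator contract (``get_params`` / ``set_params``,
fitted attributes with trailing underscores, ``check_is_fitted``), so it
composes with sklearn tooling such as ``clone``.
"""

from __future__ import annotations

from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator
from sklearn.utils.validation import check_is_fitted

from . import trends as _trends
from .lifetable import ObservedSurvival, SurvivalTable, observed_lifetable
from .model import (
    conditional_death_prob,
    predict_cumulative_survival,
    predict_interval_survival,
)
from .selection import ModelLadder, SearchConstraints, grid_search

__all__ = ["JoinpointSurvivalModel"]


class JoinpointSurvivalModel(BaseEstimator):
    """Joinpoint proportional-hazards model for survival trends.

    Fits piecewise-linear calendar-year trends on the log hazard of cancer
    death to grouped (relative, cause-specific or overall) survival data,
    choosing the number and location of joinpoints by exhaustive grid search
    and an information criterion.

    Parameters
    ----------
    max_joinpoints : int, default 0
        Largest number of joinpoints tested (up to 5).
    criterion : {"bic", "aic"}, default "bic"
        Criterion minimised to pick the final model; BIC is the more
        parsimonious choice.
    min_years_between : int, default 2
        Minimum diagnosis years between consecutive joinpoints.
    min_years_before_first, min_years_after_last : int, defaults 3 and 5
        Joinpoint-free margins at the start and end of the year range.
    max_iter : int, default 100
        IRLS iteration cap per candidate fit.
    tol : float, default 1e-8
        Relative log-likelihood convergence tolerance.
    mode : {"relative", "cause_specific", "overall"}, default "relative"
        Survival mode assumed when ``fit`` receives a bare DataFrame rather
        than a :class:`~joinpoint_survival.lifetable.SurvivalTable`.

    Attributes
    ----------
    result_ : FitResult
        The selected fit (coefficients, covariance, criteria).
    ladder_ : ModelLadder
        Best fit per number of joinpoints.
    n_joinpoints_ : int
        Selected number of joinpoints.
    joinpoints_ : ndarray of int
        Selected joinpoint calendar years.
    coef_ : ndarray
        ``(beta, delta_1..delta_K)`` — the trend coefficients.
    observed_ : ObservedSurvival
        Actuarial life-table estimates of the training data.

    Examples
    --------
    >>> from joinpoint_survival import SimulationConfig, simulate_table
    >>> cfg = SimulationConfig(year_range=(1990, 2009), beta=-0.03, seed=7)
    >>> model = JoinpointSurvivalModel(max_joinpoints=1).fit(simulate_table(cfg))
    >>> model.n_joinpoints_
    0
    """

    def __init__(
        self,
        max_joinpoints: int = 0,
        criterion: str = "bic",
        min_years_between: int = 2,
        min_years_before_first: int = 3,
        min_years_after_last: int = 5,
        max_iter: int = 100,
        tol: float = 1e-8,
        mode: str = "relative",
    ):
        self.max_joinpoints = max_joinpoints
        self.criterion = criterion
        self.min_years_between = min_years_between
        self.min_years_before_first = min_years_before_first
        self.min_years_after_last = min_years_after_last
        self.max_iter = max_iter
        self.tol = tol
        self.mode = mode

    # ------------------------------------------------------------------
    def fit(self, X: SurvivalTable | pd.DataFrame, y=None) -> "JoinpointSurvivalModel":
        """Grid-search and fit the joinpoint model on a life table.

        ``X`` is a single-cohort :class:`SurvivalTable` or a DataFrame with
        the canonical life-table columns; ``y`` is ignored (the table holds
        both design and response).
        """
        if isinstance(X, pd.DataFrame):
            X = SurvivalTable(X, mode=self.mode)
        elif not isinstance(X, SurvivalTable):
            raise TypeError("X must be a SurvivalTable or a life-table DataFrame")
        constraints = SearchConstraints(
            max_joinpoints=self.max_joinpoints,
            min_years_between=self.min_years_between,
            min_years_before_first=self.min_years_before_first,
            min_years_after_last=self.min_years_after_last,
            criterion=self.criterion,
        )
        ladder = grid_search(X, constraints, max_iter=self.max_iter, tol=self.tol)
        fit = ladder.selected
        self.ladder_: ModelLadder = ladder
        self.result_ = fit
        self.params_ = fit.params
        self.n_joinpoints_ = int(fit.n_joinpoints)
        self.joinpoints_ = fit.params.taus.copy()
        self.coef_ = np.concatenate([[fit.params.beta], fit.params.deltas])
        self.alphas_ = fit.params.alphas.copy()
        self.cov_ = fit.cov
        self.loglik_ = fit.loglik
        self.bic_ = fit.bic
        self.aic_ = fit.aic
        self.year_range_ = fit.year_range
        self.observed_: ObservedSurvival = observed_lifetable(X)
        self.n_features_in_ = 1  # calendar year is the single covariate
        return self

    # ------------------------------------------------------------------
    def predict(self, X, t: int | None = None) -> np.ndarray:
        """Cumulative survival for diagnosis years ``X`` at follow-up ``t``.

        ``X`` is an array of calendar years (in or beyond the fitted range);
        ``t`` defaults to the last fitted interval.
        """
        check_is_fitted(self, "result_")
        years = np.asarray(X, dtype=float).reshape(-1)
        if t is None:
            t = self.params_.n_intervals
        return np.asarray(
            [predict_cumulative_survival(self.params_, x, t) for x in years]
        )

    def predict_interval_survival(self, years, j: int) -> np.ndarray:
        check_is_fitted(self, "result_")
        years = np.asarray(years, dtype=float).reshape(-1)
        return np.asarray(
            [predict_interval_survival(self.params_, x, j) for x in years]
        )

    def predict_death_prob(self, years, j: int) -> np.ndarray:
        """Conditional probability of cancer death in interval ``j``."""
        check_is_fitted(self, "result_")
        years = np.asarray(years, dtype=float).reshape(-1)
        return np.asarray(
            [conditional_death_prob(self.params_, x, j) for x in years]
        )

    # ------------------------------------------------------------------
    def apc_d(self, segment: int) -> _trends.TrendEstimate:
        """Annual percent change in the probability of cancer death."""
        check_is_fitted(self, "result_")
        return _trends.apc_d(self.result_, segment)

    def aac_s(self, t: int, year_start: int | None = None,
              year_end: int | None = None, segment: int | None = None
              ) -> _trends.TrendEstimate:
        """Average annual absolute change in t-year survival (pp/year).

        Give either an explicit year window or a ``segment`` index of the
        fitted model.
        """
        check_is_fitted(self, "result_")
        if segment is not None:
            bounds = self.params_.segment_bounds(*self.year_range_)
            year_start, year_end = bounds[segment]
        if year_start is None or year_end is None:
            raise ValueError("supply segment= or both year_start and year_end")
        return _trends.aac_s(self.result_, t, year_start, year_end)

    def trend_table(self, t_values: Sequence[int] = (5, 1)) -> pd.DataFrame:
        """Per-segment AAC_S(t) and APC_D with 95% CIs and direction flags."""
        check_is_fitted(self, "result_")
        return _trends.trend_table(self.result_, t_values=t_values)

    def project(self, horizon: int = 5,
                t_values: Sequence[int] | None = None) -> pd.DataFrame:
        """Survival surface extended ``horizon`` years past the data,
        continuing the last segment's trend."""
        check_is_fitted(self, "result_")
        return _trends.project_survival(self.result_, horizon=horizon,
                                        t_values=t_values,
                                        observed=self.observed_)

    def summary(self) -> pd.DataFrame:
        """Model-ladder table (BIC/AIC/log-likelihood per joinpoint count)."""
        check_is_fitted(self, "result_")
        return self.ladder_.summary()
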