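"""Grid search over joinpoint configurations and model selection by BIC/AIC.

For each number of joinpoints ``K = 0..max_joinpoints`` every admissible
tuple of integer joinpoint years is fitted by IRLS and the best (highest
log-likelihood) converged fit is retained; the final model minimises the
chosen information criterion across the ladder.  BIC is the default: it is
the more parsimonious criterion and, in the simulations accompanying the
segmented survival model, the more reliable at recovering the true number
of joinpoints; AIC tends to select more.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

from .lifetable import SurvivalTable
from .model import FitError, FitResult, fit_fixed_joinpoints
from .model import information_criteria as _ic

__all__ = [
    "SearchConstraints",
    "ModelLadder",
    "candidate_joinpoints",
    "information_criteria",
    "grid_search",
    "select_model",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class SearchConstraints:
    """Admissibility rules for joinpoint placement.

    Attributes
    ----------
    max_joinpoints
        Largest number of joinpoints tested (0..5).
    min_years_between
        Minimum diagnosis years separating consecutive joinpoints.
    min_years_before_first
        Years at the start of the range where no joinpoint may fall.
    min_years_after_last
        Years at the end of the range where no joinpoint may fall.
    criterion
        ``"bic"`` (default) or ``"aic"``.
    """

    max_joinpoints: int = 0
    min_years_between: int = 2
    min_years_before_first: int = 3
    min_years_after_last: int = 5
    criterion: str = "bic"

    def __post_init__(self) -> None:
        if not 0 <= self.max_joinpoints <= 5:
            raise ValueError("max_joinpoints must be between 0 and 5")
        if min(self.min_years_between, self.min_years_before_first,
               self.min_years_after_last) < 1:
            raise ValueError("all joinpoint spacings must be >= 1")
        if self.criterion not in ("bic", "aic"):
            raise ValueError("criterion must be 'bic' or 'aic'")


def candidate_joinpoints(
    year_range: tuple[int, int], K: int, constraints: SearchConstraints
) -> list[tuple[int, ...]]:
    """All admissible strictly-increasing K-tuples of integer joinpoint years.

    A year ``tau`` is admissible when
    ``year_min + min_years_before_first <= tau <= year_max - min_years_after_last``
    and consecutive joinpoints differ by at least ``min_years_between``.
    ``K = 0`` yields the single empty tuple.  Output is in deterministic
    lexicographic order.
    """
    if K < 0:
        raise ValueError("K must be >= 0")
    if K == 0:
        return [()]
    lo, hi = int(year_range[0]), int(year_range[1])
    first = lo + constraints.min_years_before_first
    last = hi - constraints.min_years_after_last
    if first > last:
        raise ValueError(
            f"no admissible joinpoint years: need a year in [{first}, {last}] "
            f"(range {lo}-{hi} with edge margins "
            f"{constraints.min_years_before_first}/{constraints.min_years_after_last})"
        )
    gap = constraints.min_years_between
    out: list[tuple[int, ...]] = []
    for combo in itertools.combinations(range(first, last + 1), K):
        if K == 1 or min(b - a for a, b in zip(combo, combo[1:])) >= gap:
            out.append(combo)
    if not out:
        raise ValueError(
            f"no admissible {K}-joinpoint configuration: span {first}-{last} "
            f"cannot hold {K} joinpoints {gap} years apart"
        )
    return out


def information_criteria(fit: FitResult) -> tuple[float, float]:
    """(BIC, AIC) of a converged fit; recomputed from (loglik, p, n_cells)."""
    bic, aic = _ic(fit.loglik, fit.p, fit.n_cells)
    return float(bic), float(aic)


@dataclass
class ModelLadder:
    """Best fit for each number of joinpoints, plus the selected model.

    ``fits`` maps K to the max-likelihood converged :class:`FitResult` on the
    admissible grid for that K (ties in log-likelihood broken by the earliest
    joinpoint tuple in lexicographic order).  Numbers of joinpoints where no
    candidate converged are absent.
    """

    fits: dict[int, FitResult] = field(default_factory=dict)
    selected_k: int | None = None
    criterion: str = "bic"

    @property
    def selected(self) -> FitResult:
        if self.selected_k is None:
            raise ValueError("ladder has no selected model")
        return self.fits[self.selected_k]

    def summary(self) -> pd.DataFrame:
        """Ladder table: joinpoint count/locations, BIC, AIC, log-likelihood."""
        rows = []
        for k in sorted(self.fits):
            fit = self.fits[k]
            rows.append({
                "n_joinpoints": k,
                "joinpoints": ", ".join(str(t) for t in fit.params.taus) or "",
                "bic": fit.bic,
                "aic": fit.aic,
                "loglik": fit.loglik,
                "converged": fit.converged,
                "final_model": k == self.selected_k,
            })
        return pd.DataFrame(rows)


def grid_search(
    table: SurvivalTable,
    constraints: SearchConstraints,
    max_iter: int = 100,
    tol: float = 1e-8,
) -> ModelLadder:
    """Exhaustive grid search over joinpoint years for each K, then select.

    Candidate fits are independent (order never affects the result); the
    reported fit for each K maximises the log-likelihood among converged
    candidates, and the final model minimises the constraint's criterion.
    """
    if not table.is_single_cohort():
        raise ValueError("grid search requires a single-cohort table")
    ladder = ModelLadder(criterion=constraints.criterion)
    yr = table.year_range
    for K in range(constraints.max_joinpoints + 1):
        try:
            cands = candidate_joinpoints(yr, K, constraints)
        except ValueError as exc:
            logger.warning("K=%d infeasible: %s", K, exc)
            continue
        best: FitResult | None = None
        for taus in cands:
            try:
                fit = fit_fixed_joinpoints(table, taus, max_iter=max_iter, tol=tol)
            except FitError as exc:
                logger.debug("K=%d taus=%s failed: %s", K, taus, exc)
                continue
            if not fit.converged:
                logger.warning("K=%d taus=%s did not converge; skipped", K, taus)
                continue
            # strict > keeps the lexicographically earliest tuple on ties
            if best is None or fit.loglik > best.loglik + 0.0:
                best = fit
        if best is None:
            warnings.warn(f"no converged fit for K={K}; omitted from ladder",
                          stacklevel=2)
            continue
        ladder.fits[K] = best
    if not ladder.fits:
        raise FitError("grid search failed: no converged model at any K")
    ladder.selected_k = _argmin_criterion(ladder.fits, constraints.criterion)
    return ladder


def _argmin_criterion(fits: dict[int, FitResult], criterion: str) -> int:
    key = (lambda k: fits[k].bic) if criterion == "bic" else (lambda k: fits[k].aic)
    # sorted() keeps the smallest K on exact criterion ties
    return min(sorted(fits), key=key)


def select_model(ladder: ModelLadder, criterion: str | None = None) -> FitResult:
    """Return the converged fit minimising BIC (default) or AIC."""
    if not ladder.fits:
        raise ValueError("empty model ladder")
    crit = criterion or ladder.criterion
    if crit not in ("bic", "aic"):
        raise ValueError("criterion must be 'bic' or 'aic'")
    return ladder.fits[_argmin_criterion(ladder.fits, crit)]
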