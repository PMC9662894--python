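"""Grouped survival life tables: reading, validation, cohort selection,
and observed (actuarial) survival.

The central container is :class:`SurvivalTable`, one row per
(cohort, diagnosis year ``x``, follow-up interval ``j``) holding the counts a
cancer registry's grouped-survival export provides: number alive at the start
of the interval, number lost to follow-up during the interval, number of
deaths during the interval, and — for relative survival — the expected
interval survival of a matched general population.  Interval ``j`` is 1-based
and covers ``(j-1, j]`` years since diagnosis.

:func:`observed_lifetable` derives the standard actuarial quantities from the
counts: effective number at risk with the half-loss correction
``n_eff = n - l/2``, the observed interval death probability
``q = d / n_eff``, interval and cumulative (relative) survival, and the
Greenwood standard error of cumulative survival.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CANONICAL_COLUMNS",
    "MODES",
    "SurvivalTable",
    "ObservedSurvival",
    "LifeTableError",
    "read_survival_table",
    "write_survival_table",
    "select_cohort",
    "observed_lifetable",
]

#: Canonical column names of the delimited dialect, in writing order.
CANONICAL_COLUMNS = (
    "Year",
    "Interval",
    "Alive_at_Start",
    "Lost_to_Followup",
    "Died",
    "Expected_Survival_Interval",
)

#: Supported survival modes.
MODES = ("relative", "cause_specific", "overall")


class LifeTableError(ValueError):
    """A life table violated a structural invariant, or a column is missing."""


@dataclass(frozen=True)
class SurvivalTable:
    """Validated grouped survival data.

    Parameters
    ----------
    data
        One row per (cohort, year, interval) with the canonical columns of
        :data:`CANONICAL_COLUMNS` plus any stratifier columns.
    mode
        ``"relative"``, ``"cause_specific"`` or ``"overall"``.  In relative
        mode ``Expected_Survival_Interval`` must lie in (0, 1]; otherwise it
        is carried but ignored.
    strata_cols
        Names of the stratifier columns (e.g. site, sex, stage) that define
        cohorts; empty for a single-cohort table.
    """

    data: pd.DataFrame
    mode: str = "relative"
    strata_cols: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.mode not in MODES:
            raise LifeTableError(
                f"mode must be one of {MODES}, got {self.mode!r}"
            )
        object.__setattr__(self, "strata_cols", tuple(self.strata_cols))
        df = _validate_frame(self.data, self.mode, self.strata_cols)
        object.__setattr__(self, "data", df)

    # -- metadata ---------------------------------------------------------
    @property
    def year_range(self) -> tuple[int, int]:
        years = self.data["Year"]
        return int(years.min()), int(years.max())

    @property
    def years(self) -> np.ndarray:
        return np.sort(self.data["Year"].unique())

    @property
    def max_interval(self) -> int:
        return int(self.data["Interval"].max())

    @property
    def n_cells(self) -> int:
        """Number of (year, interval) data cells — the BIC sample size."""
        return len(self.data)

    def is_single_cohort(self) -> bool:
        if not self.strata_cols:
            return True
        return not self.data[list(self.strata_cols)].drop_duplicates().shape[0] > 1

    def cohorts(self) -> pd.DataFrame:
        """Distinct stratifier combinations present, one row each."""
        if not self.strata_cols:
            return pd.DataFrame(index=[0])
        return (
            self.data[list(self.strata_cols)]
            .drop_duplicates()
            .reset_index(drop=True)
        )


def _validate_frame(
    df: pd.DataFrame, mode: str, strata_cols: Sequence[str]
) -> pd.DataFrame:
    missing = [c for c in CANONICAL_COLUMNS[:5] if c not in df.columns]
    if mode == "relative" and "Expected_Survival_Interval" not in df.columns:
        missing.append("Expected_Survival_Interval")
    if missing:
        raise LifeTableError(f"missing required column(s): {', '.join(missing)}")
    for c in strata_cols:
        if c not in df.columns:
            raise LifeTableError(f"stratifier column {c!r} not in data")

    df = df.copy()
    if "Expected_Survival_Interval" not in df.columns:
        df["Expected_Survival_Interval"] = 1.0

    for col in ("Year", "Interval"):
        vals = df[col].to_numpy()
        as_int = np.asarray(vals, dtype=float)
        if not np.all(np.isfinite(as_int)) or not np.all(as_int == np.round(as_int)):
            bad = int(np.flatnonzero(~(as_int == np.round(as_int)))[0])
            raise LifeTableError(f"non-integer {col} at row {bad}")
        df[col] = as_int.astype(int)
    for col in ("Alive_at_Start", "Lost_to_Followup", "Died"):
        vals = np.asarray(df[col].to_numpy(), dtype=float)
        if np.any(~np.isfinite(vals)) or np.any(vals < 0):
            bad = int(np.flatnonzero(~np.isfinite(vals) | (vals < 0))[0])
            raise LifeTableError(f"negative or missing {col} at row {bad}")
        df[col] = vals
    if np.any(df["Interval"].to_numpy() < 1):
        raise LifeTableError("Interval indices must be >= 1")

    e = np.asarray(df["Expected_Survival_Interval"].to_numpy(), dtype=float)
    if mode == "relative" and (np.any(~np.isfinite(e)) or np.any(e <= 0) or np.any(e > 1)):
        bad = int(np.flatnonzero(~np.isfinite(e) | (e <= 0) | (e > 1))[0])
        raise LifeTableError(
            f"Expected_Survival_Interval outside (0, 1] at row {bad}"
        )

    n = df["Alive_at_Start"].to_numpy()
    d = df["Died"].to_numpy()
    lost = df["Lost_to_Followup"].to_numpy()
    if np.any(n < d + lost):
        bad = int(np.flatnonzero(n < d + lost)[0])
        raise LifeTableError(
            f"Alive_at_Start < Died + Lost_to_Followup at row {bad}"
        )

    keys = list(strata_cols) + ["Year", "Interval"]
    if df.duplicated(subset=keys).any():
        dup = df[df.duplicated(subset=keys)].iloc[0]
        raise LifeTableError(
            f"duplicate (year, interval) cell: Year={dup['Year']}, "
            f"Interval={dup['Interval']}"
        )

    df = df.sort_values(keys, kind="mergesort").reset_index(drop=True)

    # coherence: within a cohort-year, successive at-risk counts must chain
    group_keys = list(strata_cols) + ["Year"] if strata_cols else ["Year"]
    for gkey, grp in df.groupby(group_keys, sort=False):
        iv = grp["Interval"].to_numpy()
        if np.any(np.diff(iv) != 1) or iv[0] != 1:
            raise LifeTableError(
                f"intervals for cohort/year {gkey} are not contiguous from 1"
            )
        at_risk = grp["Alive_at_Start"].to_numpy()
        removed = grp["Died"].to_numpy() + grp["Lost_to_Followup"].to_numpy()
        if np.any(at_risk[1:] > at_risk[:-1] - removed[:-1]):
            j = int(np.flatnonzero(at_risk[1:] > at_risk[:-1] - removed[:-1])[0])
            raise LifeTableError(
                f"life table incoherent for cohort/year {gkey} between "
                f"intervals {iv[j]} and {iv[j + 1]}: at-risk exceeds "
                "previous at-risk minus removals"
            )
    return df


def read_survival_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
    mode: str = "relative",
    dialect: str | None = None,
    strata_cols: Sequence[str] = (),
) -> SurvivalTable:
    """Read a delimited grouped-survival file into a :class:`SurvivalTable`.

    Parameters
    ----------
    path
        CSV or TSV file with a header row.
    column_map
        Mapping from canonical name to the file's column name, e.g.
        ``{"Year": "Year of diagnosis"}``.  Unmapped canonical names are
        looked up directly.
    mode
        Survival mode; relative mode requires the expected-survival column.
    dialect
        ``","`` or ``"\\t"``; sniffed from the extension/content if omitted.
    strata_cols
        Stratifier columns (file-side names are remapped like the others).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect is None:
        with open(path) as fh:
            header = fh.readline()
        dialect = "\t" if "\t" in header else ","
    df = pd.read_csv(path, sep=dialect)
    if column_map:
        missing = [src for src in column_map.values() if src not in df.columns]
        if missing:
            raise LifeTableError(
                f"mapped column(s) not found in file: {', '.join(missing)}"
            )
        df = df.rename(columns={v: k for k, v in column_map.items()})
    return SurvivalTable(df, mode=mode, strata_cols=tuple(strata_cols))


def write_survival_table(
    table: SurvivalTable, path: str | Path, dialect: str = ","
) -> None:
    """Write a table in the canonical delimited dialect (header included)."""
    cols = list(table.strata_cols) + list(CANONICAL_COLUMNS)
    table.data[cols].to_csv(path, sep=dialect, index=False)


def select_cohort(
    table: SurvivalTable,
    strata_filter: Mapping[str, object] | None = None,
    year_min: int | None = None,
    year_max: int | None = None,
    max_followup: int | None = None,
) -> SurvivalTable:
    """Restrict a table to one cohort, a diagnosis-year window, and a maximum
    follow-up interval.

    Raises if the selection is empty or if the filter leaves more than one
    stratifier combination (downstream fitting is single-cohort).
    """
    if strata_filter:
        unknown = [k for k in strata_filter if k not in table.strata_cols]
        if unknown:
            raise LifeTableError(
                f"filter key(s) not among stratifiers: {', '.join(unknown)}"
            )
    lo, hi = table.year_range
    year_min = lo if year_min is None else int(year_min)
    year_max = hi if year_max is None else int(year_max)
    if year_min > year_max:
        raise LifeTableError("year_min exceeds year_max")
    if max_followup is not None and max_followup < 1:
        raise LifeTableError("max_followup must be >= 1")

    df = table.data
    mask = (df["Year"] >= year_min) & (df["Year"] <= year_max)
    if max_followup is not None:
        mask &= df["Interval"] <= max_followup
    if strata_filter:
        for k, v in strata_filter.items():
            mask &= df[k] == v
    sub = df[mask]
    if sub.empty:
        raise LifeTableError("cohort selection is empty")
    out = SurvivalTable(sub.reset_index(drop=True), mode=table.mode,
                        strata_cols=table.strata_cols)
    if not out.is_single_cohort():
        raise LifeTableError(
            "selection matches more than one cohort; add stratifier filters"
        )
    return out


@dataclass(frozen=True)
class ObservedSurvival:
    """Actuarial life-table estimates derived from a :class:`SurvivalTable`.

    ``data`` has one row per (cohort, Year, Interval) with columns:

    ``n_eff``
        effective number at risk, ``Alive_at_Start - Lost_to_Followup / 2``
    ``q_obs``
        observed interval death probability ``Died / n_eff``
    ``s_obs_interval``
        observed all-cause interval survival ``1 - q_obs``
    ``r_obs_interval``
        observed interval relative survival (relative mode; may exceed 1)
    ``S_obs_cum``
        cumulative survival at the end of the interval (relative survival in
        relative mode, net survival otherwise), the running product of the
        interval values
    ``se_S``
        Greenwood standard error of ``S_obs_cum``
    """

    data: pd.DataFrame
    mode: str = "relative"
    strata_cols: tuple[str, ...] = ()


def observed_lifetable(table: SurvivalTable) -> ObservedSurvival:
    """Compute actuarial interval/cumulative survival with Greenwood SEs.

    The half-loss exposure correction treats each case lost to follow-up as
    at risk for half the interval.  In relative mode the interval estimate is
    divided by the expected interval survival; values above 1 are retained.
    A ``q_obs >= 1`` on a non-final interval is flagged (column ``flagged``)
    with a warning rather than raising, since it merely signals a cohort
    whose observed survival hits zero early.
    """
    df = table.data.copy()
    # rows with nobody at risk carry no information; drop rather than divide
    df = df[df["Alive_at_Start"] > 0].reset_index(drop=True)
    n_eff = df["Alive_at_Start"].to_numpy(float) - df["Lost_to_Followup"].to_numpy(float) / 2.0
    if np.any(n_eff <= 0):
        bad = int(np.flatnonzero(n_eff <= 0)[0])
        raise LifeTableError(
            f"effective at-risk count is non-positive at row {bad} "
            f"(Year={df['Year'].iat[bad]}, Interval={df['Interval'].iat[bad]})"
        )
    q = df["Died"].to_numpy(float) / n_eff
    s_int = 1.0 - q
    df["n_eff"] = n_eff
    df["q_obs"] = q
    df["s_obs_interval"] = s_int
    if table.mode == "relative":
        df["r_obs_interval"] = s_int / df["Expected_Survival_Interval"].to_numpy(float)
    else:
        df["r_obs_interval"] = s_int

    group_keys = (list(table.strata_cols) + ["Year"]) if table.strata_cols else ["Year"]
    df["S_obs_cum"] = df.groupby(group_keys, sort=False)["r_obs_interval"].cumprod()

    # Greenwood: var(S)/S^2 accumulates q / (n_eff * (1 - q))
    with np.errstate(divide="ignore", invalid="ignore"):
        inc = np.where(s_int > 0, q / (n_eff * np.clip(s_int, 1e-300, None)), np.inf)
    df["_gw"] = inc
    cum_gw = df.groupby(group_keys, sort=False)["_gw"].cumsum()
    df["se_S"] = np.abs(df["S_obs_cum"]) * np.sqrt(cum_gw)
    df = df.drop(columns="_gw")

    # flag degenerate cohorts: survival hits zero before the cohort's last
    # tabulated interval (the year's own rows necessarily stop there)
    if table.strata_cols:
        max_iv = df.groupby(list(table.strata_cols), sort=False)["Interval"].transform("max")
    else:
        max_iv = pd.Series(df["Interval"].max(), index=df.index)
    flagged = (q >= 1.0) & (df["Interval"] < max_iv)
    df["flagged"] = flagged
    if flagged.any():
        warnings.warn(
            f"{int(flagged.sum())} non-final interval(s) with observed death "
            "probability >= 1; survival hits zero before the last interval",
            stacklevel=2,
        )
    return ObservedSurvival(df, mode=table.mode, strata_cols=table.strata_cols)
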