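"""Condition-level time series from per-cell records.

Aggregates per-cell records into population mean/SD series per
parameter (the per-condition time-series panels), z-scores each series
in preparation for spectral analysis, and computes the 11×11
parameter–parameter correlation matrix of a condition.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .params import PARAM_KEYS

logger = logging.getLogger(__name__)


@dataclass
class ConditionSeries:
    """Population mean/SD per parameter over cycles for one condition.

    ``mean`` and ``sd`` are DataFrames indexed by cycle with one column
    per parameter; ``n_cells`` the per-cycle population size;
    ``filled_cycles`` lists cycles with no alive cells, filled by
    last-observation-carried-forward.
    """

    condition: str
    mean: pd.DataFrame
    sd: pd.DataFrame
    n_cells: pd.Series
    filled_cycles: list[int] = field(default_factory=list)

    @property
    def cycles(self) -> np.ndarray:
        return self.mean.index.to_numpy()


@dataclass
class CenteredSeries:
    """Z-scored (sample SD, zero mean) population-mean series per
    parameter, with location/scale retained for inversion."""

    condition: str
    values: pd.DataFrame  # cycles × parameters, each column mean 0 / sd 1
    location: pd.Series
    scale: pd.Series

    def invert(self) -> pd.DataFrame:
        return self.values * self.scale + self.location


def aggregate(records: pd.DataFrame) -> dict[str, ConditionSeries]:
    """Population mean/SD (n−1 denominator) at each cycle per condition.

    Cycles between the first and last observed cycle with no alive cells
    are filled by carrying the last observation forward and flagged in
    ``filled_cycles``.  Single-cell cycles get SD 0 with a warning.
    """
    if records is None or len(records) == 0:
        raise ValueError("no records to aggregate")
    alive = records[records["alive"]] if "alive" in records else records
    out: dict[str, ConditionSeries] = {}
    for cond, g in alive.groupby("condition", sort=True):
        if len(g) == 0:
            raise ValueError(f"condition {cond!r} has zero records")
        grouped = g.groupby("cycle")
        mean = grouped[list(PARAM_KEYS)].mean()
        sd = grouped[list(PARAM_KEYS)].std(ddof=1)
        n = grouped["cell_id"].nunique()
        sd[n == 1] = 0.0
        if (n == 1).any():
            logger.warning("condition %s: %d single-cell cycles (SD set to 0)",
                           cond, int((n == 1).sum()))
        full = pd.RangeIndex(int(mean.index.min()), int(mean.index.max()) + 1,
                             name="cycle")
        filled = sorted(set(full) - set(mean.index))
        if filled:
            logger.warning("condition %s: %d empty cycles filled by LOCF",
                           cond, len(filled))
            mean = mean.reindex(full).ffill()
            sd = sd.reindex(full).ffill()
            n = n.reindex(full).fillna(0).astype(int)
        out[cond] = ConditionSeries(condition=str(cond), mean=mean, sd=sd,
                                    n_cells=n, filled_cycles=list(filled))
    return out


def center_scale(series: ConditionSeries, center: bool = True,
                 scale: bool = True) -> CenteredSeries:
    """Z-score each parameter's population-mean series over cycles.

    Matches the conventional centering+scaling of a data matrix before
    spectral analysis: per column, subtract the mean and divide by the
    sample standard deviation.  A zero-variance series carries no
    frequency information and raises ``ValueError``.
    """
    loc = series.mean.mean(axis=0) if center else pd.Series(0.0, index=series.mean.columns)
    sc = series.mean.std(axis=0, ddof=1) if scale else pd.Series(1.0, index=series.mean.columns)
    if scale:
        dead = sc[sc == 0]
        if len(dead):
            raise ValueError(
                f"zero-variance series for condition {series.condition!r}, "
                f"parameter(s) {list(dead.index)}: cannot scale a constant series"
            )
    values = (series.mean - loc) / sc
    return CenteredSeries(condition=series.condition, values=values,
                          location=loc, scale=sc)


def parameter_correlation(series: ConditionSeries) -> pd.DataFrame:
    """Pearson correlation between every pair of parameter mean-series.

    Zero-variance parameters get NaN rows/columns (logged); the diagonal
    stays 1 for well-defined parameters.
    """
    if len(series.mean) < 3:
        raise ValueError("need at least 3 cycles for a correlation matrix")
    m = series.mean[list(PARAM_KEYS)]
    sd = m.std(axis=0, ddof=1)
    degenerate = list(sd[sd == 0].index)
    if degenerate:
        logger.warning("condition %s: zero-variance parameter(s) %s in "
                       "correlation matrix", series.condition, degenerate)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(m.to_numpy(), rowvar=False)
    out = pd.DataFrame(corr, index=m.columns, columns=m.columns)
    for p in degenerate:
        out.loc[p, :] = np.nan
        out.loc[:, p] = np.nan
    return out
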