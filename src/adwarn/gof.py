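"""Goodness-of-fit metrics between measured and simulated daily series.

Two complementary metrics:

* rRMSE = (1 / ybar_exp) * sqrt( (1/n) * sum (y_exp - y_sim)^2 ), the root
  mean squared error relative to the mean of the measurements (0 = perfect,
  unbounded above, sensitive to large errors);
* MAPE = (100 / n) * sum |y_exp - y_sim| / y_exp, in %, less distorted by
  extreme points; simulations are customarily called reliable below 50%.

Both are evaluated per process variable over configurable day windows
(default 0-165 and 30-165, the second excluding the stochastic start-up).
Measurements are the reference: the (dense) simulated series is linearly
interpolated at the measured days, never the reverse.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["GoFReport", "rrmse", "mape", "evaluate_windows", "DEFAULT_WINDOWS"]

DEFAULT_WINDOWS: tuple[tuple[int, int], ...] = ((0, 165), (30, 165))


@dataclass(frozen=True)
class GoFReport:
    variable: str
    window: tuple[int, int]
    n: int
    ybar_exp: float
    rrmse: float
    mape: float  # %
    mape_excluded: int = 0  # zero-measurement points dropped from MAPE


def rrmse(y_exp, y_sim) -> float:
    """Relative root mean squared error (unitless)."""
    y_exp = np.asarray(y_exp, dtype=float)
    y_sim = np.asarray(y_sim, dtype=float)
    if y_exp.shape != y_sim.shape or y_exp.size == 0:
        raise ValueError("inputs must be equal-length, nonempty vectors")
    ybar = y_exp.mean()
    if ybar == 0:
        raise ZeroDivisionError("rRMSE undefined: mean of measurements is zero")
    return float(np.sqrt(np.mean((y_exp - y_sim) ** 2)) / ybar)


def mape(y_exp, y_sim, return_excluded: bool = False):
    """Mean absolute percentage error in %.

    Zero-valued measurements make their term undefined and are dropped;
    pass ``return_excluded=True`` to also get the number of dropped points.
    """
    y_exp = np.asarray(y_exp, dtype=float)
    y_sim = np.asarray(y_sim, dtype=float)
    if y_exp.shape != y_sim.shape or y_exp.size == 0:
        raise ValueError("inputs must be equal-length, nonempty vectors")
    keep = y_exp != 0
    excluded = int((~keep).sum())
    if not keep.any():
        raise ZeroDivisionError("MAPE undefined: every measurement is zero")
    value = float(100.0 * np.mean(np.abs((y_exp[keep] - y_sim[keep]) / y_exp[keep])))
    return (value, excluded) if return_excluded else value


def evaluate_windows(
    exp_series: pd.DataFrame,
    sim_series: pd.DataFrame,
    variables: list[str] | None = None,
    windows: tuple[tuple[int, int], ...] = DEFAULT_WINDOWS,
) -> list[GoFReport]:
    """One GoF report per variable per (inclusive) day window.

    Both frames need a ``day`` column; ``variables`` defaults to all columns
    shared by the two frames (minus ``day``).  The simulated series is
    interpolated at the measured days before pairing.
    """
    if variables is None:
        variables = [c for c in exp_series.columns if c != "day" and c in sim_series.columns]
    exp_day = exp_series["day"].to_numpy(dtype=float)
    sim_day = sim_series["day"].to_numpy(dtype=float)
    out: list[GoFReport] = []
    for var in variables:
        ye_all = exp_series[var].to_numpy(dtype=float)
        ys_dense = sim_series[var].to_numpy(dtype=float)
        ok_sim = np.isfinite(ys_dense)
        for lo, hi in windows:
            mask = (exp_day >= lo) & (exp_day <= hi) & np.isfinite(ye_all)
            if not mask.any():
                raise ValueError(f"window {lo}-{hi} contains no measured day for {var!r}")
            de = exp_day[mask]
            ye = ye_all[mask]
            ys = np.interp(de, sim_day[ok_sim], ys_dense[ok_sim])
            m, excl = mape(ye, ys, return_excluded=True)
            out.append(
                GoFReport(
                    variable=var,
                    window=(lo, hi),
                    n=int(mask.sum()),
                    ybar_exp=float(ye.mean()),
                    rrmse=rrmse(ye, ys),
                    mape=m,
                    mape_excluded=excl,
                )
            )
    return out
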