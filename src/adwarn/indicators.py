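"""Early-warning indicator screening for anaerobic digesters.

The screening logic works on daily indicator series and follows four rules:

* *pairwise RSD*: the fluctuation statistic between consecutive days,
  RSD = S / x_bar * 100 with S = sqrt((x_t - x_bar)^2 + (x_{t-1} - x_bar)^2)
  and x_bar the mean of the two days (no n-1 divisor) - algebraically
  |x_t - x_{t-1}| / (sqrt(2) * x_bar) * 100;
* *steady state*: at least 6 consecutive days of daily biogas production
  within +/-10% variation;
* *process failure*: the first day with pH < 6.4, or a day-on-day *drop* in
  CH4 yield with RSD > 20%;
* *abrupt change*: the first day inside an overload window where an
  indicator moves in its acidification direction with RSD > 20%
  (10-20% days are reported as "slight" instability).

Warning time is the number of days between an indicator's abrupt change
and process failure.  Amplitudes of abrupt changes are expressed relative
to steady-state extremes: (reference - extreme) / extreme * 100.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .schedules import OperationSchedule

__all__ = [
    "DIRECTIONS",
    "SteadyStatePeriod",
    "ChangeEvent",
    "IndicatorReport",
    "ScreeningReport",
    "ScreeningThresholds",
    "EXPERIMENTAL_THRESHOLDS",
    "SIMULATED_THRESHOLDS",
    "rsd_pair",
    "rsd_series",
    "detect_steady_periods",
    "detect_failure",
    "detect_abrupt_change",
    "warning_time",
    "amplitude_range",
    "screen",
    "indicators_from_measurements",
]

PH_FAILURE_LIMIT = 6.4
RSD_ABRUPT = 20.0  # %
RSD_SLIGHT = 10.0  # %
STEADY_TOL = 0.10
STEADY_MIN_DAYS = 6

# acidification direction: +1 rises when the digester sours, -1 falls
DIRECTIONS: dict[str, int] = {
    "ch4_yield": -1,
    "ch4_co2": -1,
    "acetate": +1,
    "propionate": +1,
    "butyrate": +1,
    "vfa_total": +1,
    "IA": +1,
    "BA": -1,
    "TA": -1,
    "ia_ba": +1,
    "ba_ta": -1,
    "vfa_ba": +1,
    "ph": -1,
}

# indicators screened by the RSD rule (pH is handled only by the 6.4 rule)
SCREENED = [n for n in DIRECTIONS if n not in ("ph", "TA", "ch4_yield")]

_MEASUREMENT_COLUMNS = {
    "ch4_yield": "ch4_yield_L_per_gVS",
    "acetate": "ac_gL",
    "propionate": "pro_gL",
    "butyrate": "bu_gL",
    "vfa_total": "vfa_gL",
    "IA": "ia_mgCaCO3L",
    "BA": "ba_mgCaCO3L",
    "TA": "ta_mgCaCO3L",
    "ph": "ph",
}


def rsd_pair(x_curr: float, x_prev: float) -> float:
    """Pairwise relative standard deviation in % (NaN when the mean is 0)."""
    xbar = (x_curr + x_prev) / 2.0
    if xbar == 0 or not math.isfinite(xbar):
        return math.nan
    s = math.sqrt((x_curr - xbar) ** 2 + (x_prev - xbar) ** 2)
    return s / xbar * 100.0


def rsd_series(values: pd.Series) -> pd.Series:
    """Pairwise RSD of each day versus the previous day (first day NaN)."""
    v = values.to_numpy(dtype=float)
    out = np.full(v.shape, np.nan)
    for i in range(1, len(v)):
        out[i] = rsd_pair(v[i], v[i - 1])
    return pd.Series(out, index=values.index)


@dataclass(frozen=True)
class SteadyStatePeriod:
    start_day: int
    end_day: int  # inclusive
    mean: float
    minimum: float
    maximum: float

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day + 1

    def extreme(self, direction: int) -> float:
        return self.maximum if direction > 0 else self.minimum


def detect_steady_periods(
    series: pd.Series,
    tol: float = STEADY_TOL,
    min_days: int = STEADY_MIN_DAYS,
    rule: str = "mean_band",
) -> list[SteadyStatePeriod]:
    """Maximal runs of >= ``min_days`` consecutive days of steady operation.

    ``series`` is indexed by day.  With the default ``mean_band`` rule a run
    is steady while every daily value stays within +/-``tol`` of the
    running-window mean (greedy extension, non-overlapping).  The
    ``day_to_day`` alternative instead requires the pairwise RSD of every
    consecutive pair to stay below ``tol*100`` %.
    """
    days = np.asarray(series.index, dtype=int)
    vals = series.to_numpy(dtype=float)
    if np.any(np.diff(days) != 1):
        # split on gaps and recurse per contiguous block
        out: list[SteadyStatePeriod] = []
        start = 0
        for i in range(1, len(days) + 1):
            if i == len(days) or days[i] != days[i - 1] + 1:
                out.extend(detect_steady_periods(series.iloc[start:i], tol, min_days, rule))
                start = i
        return out

    periods: list[SteadyStatePeriod] = []
    i = 0
    n = len(vals)
    while i < n:
        j = i + 1
        while j <= n:
            window = vals[i:j]
            if rule == "mean_band":
                m = window.mean()
                ok = m != 0 and np.all(np.abs(window - m) <= tol * abs(m))
            elif rule == "day_to_day":
                ok = all(
                    rsd_pair(window[k], window[k - 1]) <= tol * 100.0
                    for k in range(1, len(window))
                )
            else:
                raise ValueError(f"unknown steady-state rule {rule!r}")
            if not ok:
                break
            j += 1
        j -= 1  # last j with a steady window [i, j)
        if j - i >= min_days:
            w = vals[i:j]
            periods.append(
                SteadyStatePeriod(
                    start_day=int(days[i]),
                    end_day=int(days[j - 1]),
                    mean=float(w.mean()),
                    minimum=float(w.min()),
                    maximum=float(w.max()),
                )
            )
            i = j
        else:
            i += 1
    return periods


def detect_failure(ph: pd.Series, ch4_yield: pd.Series | None = None) -> int | None:
    """Earliest failure day: pH < 6.4, or a >20%-RSD day-on-day CH4-yield drop."""
    fail_days: list[int] = []
    below = ph[ph < PH_FAILURE_LIMIT]
    if len(below):
        fail_days.append(int(below.index[0]))
    if ch4_yield is not None and len(ch4_yield) > 1:
        v = ch4_yield.to_numpy(dtype=float)
        days = np.asarray(ch4_yield.index, dtype=int)
        for i in range(1, len(v)):
            r = rsd_pair(v[i], v[i - 1])
            if math.isfinite(r) and r > RSD_ABRUPT and v[i] < v[i - 1]:
                fail_days.append(int(days[i]))
                break
    return min(fail_days) if fail_days else None


@dataclass(frozen=True)
class ChangeEvent:
    day: int
    value: float
    rsd: float  # %
    slight_days: tuple[int, ...] = ()  # 10-20% RSD days in the window


def detect_abrupt_change(
    series: pd.Series,
    window: tuple[int, int],
    direction: int,
    threshold: float = RSD_ABRUPT,
    slight: float = RSD_SLIGHT,
) -> ChangeEvent | None:
    """First day in the inclusive window with RSD > threshold in the
    indicator's acidification direction; also collects 10-20% "slight" days.
    """
    lo, hi = window
    days = np.asarray(series.index, dtype=int)
    vals = series.to_numpy(dtype=float)
    slight_days: list[int] = []
    hit: ChangeEvent | None = None
    for i in range(1, len(vals)):
        d = int(days[i])
        if d < lo or d > hi:
            continue
        r = rsd_pair(vals[i], vals[i - 1])
        if not math.isfinite(r):
            continue
        step = vals[i] - vals[i - 1]
        right_way = step * direction > 0
        if r > threshold and right_way and hit is None:
            hit = ChangeEvent(day=d, value=float(vals[i]), rsd=float(r))
        elif slight < r <= threshold and right_way:
            slight_days.append(d)
    if hit is None:
        return None
    return ChangeEvent(hit.day, hit.value, hit.rsd, tuple(slight_days))


def warning_time(abrupt_day: int, failure_day: int) -> tuple[int, bool]:
    """Days between abrupt change and failure; flags abrupt-after-failure.

    Returns ``(days, late_flag)``; an abrupt change after failure reports 0
    with ``late_flag=True``.
    """
    if failure_day < abrupt_day:
        return 0, True
    return failure_day - abrupt_day, False


def amplitude_range(
    reference_value: float,
    periods: list[SteadyStatePeriod],
    direction: int,
) -> tuple[float, float]:
    """Percentagewise change of the reference (abrupt) value against every
    steady-state extreme: (reference - extreme) / extreme * 100.

    Rising indicators are compared against each period's maximum, falling
    ones against the minimum; the result is the (lowest, highest) change.
    When every period shows the same change, the comparison is redone
    against period means and that single value is returned for both bounds.
    """
    if not periods:
        raise ValueError("amplitude_range needs at least one steady-state period")
    changes = []
    for p in periods:
        extreme = p.extreme(direction)
        if extreme == 0:
            continue
        changes.append((reference_value - extreme) / extreme * 100.0)
    if not changes:
        raise ValueError("all steady-state extremes are zero")
    lo, hi = min(changes), max(changes)
    if math.isclose(lo, hi, rel_tol=0.0, abs_tol=1e-12):
        means = [
            (reference_value - p.mean) / p.mean * 100.0 for p in periods if p.mean != 0
        ]
        avg = float(np.mean(means)) if means else lo
        return avg, avg
    return lo, hi


@dataclass(frozen=True)
class ScreeningThresholds:
    """Amplitude thresholds (in %, signed by acidification direction)."""

    by_indicator: dict[str, float]

    def scaled(self, factor: float) -> "ScreeningThresholds":
        return ScreeningThresholds({k: v * factor for k, v in self.by_indicator.items()})


EXPERIMENTAL_THRESHOLDS = ScreeningThresholds(
    {"ia_ba": +10.0, "vfa_total": +51.0, "IA": +20.0, "BA": -11.0, "vfa_ba": +30.0}
)
SIMULATED_THRESHOLDS = ScreeningThresholds(
    {"ia_ba": +20.0, "vfa_total": +19.0, "IA": +20.0, "BA": -11.0, "vfa_ba": +30.0}
)


@dataclass
class IndicatorReport:
    indicator: str
    window: tuple[int, int]
    abrupt_change_day: int | None = None
    abrupt_value: float | None = None
    abrupt_rsd: float | None = None
    slight_days: tuple[int, ...] = ()
    failure_day: int | None = None
    warning_time: int | None = None
    late_flag: bool = False
    amplitude_min: float | None = None
    amplitude_max: float | None = None
    fullload_rsd_mean: float | None = None
    risk_flag: bool = False


@dataclass
class ScreeningReport:
    mode: str
    failure_day: int | None
    steady_periods: list[SteadyStatePeriod]
    records: list[IndicatorReport] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    def record(self, indicator: str, window: tuple[int, int]) -> IndicatorReport | None:
        for r in self.records:
            if r.indicator == indicator and r.window == window:
                return r
        return None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([vars(r) for r in self.records])

    def summary(self) -> str:
        lines = [
            f"screening mode: {self.mode}",
            f"process failure day: {self.failure_day}",
            f"steady-state periods: "
            + (", ".join(f"{p.start_day}-{p.end_day}" for p in self.steady_periods) or "none"),
        ]
        for r in self.records:
            amp = (
                f"{r.amplitude_min:+.0f}% to {r.amplitude_max:+.0f}%"
                if r.amplitude_min is not None
                else "n/a"
            )
            lines.append(
                f"  [{r.window[0]}-{r.window[1]}] {r.indicator:<10} "
                f"abrupt={r.abrupt_change_day} warn={r.warning_time} "
                f"amplitude={amp} risk={'YES' if r.risk_flag else 'no'}"
            )
        lines.extend("  ! " + w for w in self.warnings)
        return "\n".join(lines)


def indicators_from_measurements(df: pd.DataFrame) -> pd.DataFrame:
    """Indicator frame (one column per named indicator, day index) from the
    shared daily measurement table.  Ratio indicators are computed from base
    columns when not already present."""
    out = pd.DataFrame(index=pd.Index(df["day"].astype(int), name="day"))
    # columns already carrying indicator names pass straight through
    for name in DIRECTIONS:
        if name in df.columns:
            out[name] = df[name].to_numpy(dtype=float)
    for name, col in _MEASUREMENT_COLUMNS.items():
        if name not in out.columns and col in df.columns:
            out[name] = df[col].to_numpy(dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        if "ch4_co2" not in out and {"ch4_frac", "co2_frac"} <= set(df.columns):
            co2 = df["co2_frac"].to_numpy(dtype=float)
            out["ch4_co2"] = np.where(co2 > 0, df["ch4_frac"].to_numpy(dtype=float) / co2, np.nan)
        if "ia_ba" not in out and {"IA", "BA"} <= set(out.columns):
            out["ia_ba"] = out["IA"] / out["BA"]
        if "ba_ta" not in out and {"BA", "TA"} <= set(out.columns):
            out["ba_ta"] = out["BA"] / out["TA"]
        if "vfa_ba" not in out and {"vfa_total", "BA"} <= set(out.columns):
            out["vfa_ba"] = out["vfa_total"] / (out["BA"] / 1000.0)
    if "biogas_L" in df.columns:
        out["biogas_L"] = df["biogas_L"].to_numpy(dtype=float)
    return out


def screen(
    frame: pd.DataFrame,
    schedule: OperationSchedule,
    mode: str = "experimental",
    thresholds: ScreeningThresholds | None = None,
    indicators: list[str] | None = None,
) -> ScreeningReport:
    """Run the full screening pipeline on an indicator frame.

    ``frame`` has a day index and one column per indicator name (see
    :func:`indicators_from_measurements`); ``biogas_L`` drives steady-state
    detection.  One :class:`IndicatorReport` is produced per screened
    indicator per overload window of the schedule.
    """
    if mode not in ("experimental", "simulated"):
        raise ValueError("mode must be 'experimental' or 'simulated'")
    if thresholds is None:
        thresholds = EXPERIMENTAL_THRESHOLDS if mode == "experimental" else SIMULATED_THRESHOLDS

    report = ScreeningReport(mode=mode, failure_day=None, steady_periods=[])

    if "biogas_L" in frame.columns:
        report.steady_periods = detect_steady_periods(frame["biogas_L"].dropna())
    else:
        report.warnings.append("no biogas_L column: steady-state detection skipped")

    if "ph" in frame.columns:
        ch4y = frame["ch4_yield"].dropna() if "ch4_yield" in frame.columns else None
        report.failure_day = detect_failure(frame["ph"].dropna(), ch4y)
    else:
        report.warnings.append("no ph column: failure detection skipped")

    windows = schedule.windows("gradual_overload") + schedule.windows("sudden_overload")
    fullload = schedule.windows("full_load")
    names = indicators if indicators is not None else [n for n in SCREENED if n in frame.columns]

    for name in names:
        series = frame[name].dropna()
        direction = DIRECTIONS[name]
        rsd = rsd_series(series)
        fl_vals = [
            rsd.loc[(rsd.index >= lo) & (rsd.index <= hi)].dropna() for lo, hi in fullload
        ]
        fl_mean = float(pd.concat(fl_vals).mean()) if fl_vals else None
        for window in windows:
            rec = IndicatorReport(indicator=name, window=window, fullload_rsd_mean=fl_mean)
            rec.failure_day = report.failure_day
            event = detect_abrupt_change(series, window, direction)
            if event is not None:
                rec.abrupt_change_day = event.day
                rec.abrupt_value = event.value
                rec.abrupt_rsd = event.rsd
                rec.slight_days = event.slight_days
                if report.failure_day is not None:
                    rec.warning_time, rec.late_flag = warning_time(event.day, report.failure_day)
                # reference periods: steady stretches before the overload
                # window (a period running into the window is clipped at it)
                pre = [
                    (p.start_day, min(p.end_day, window[0] - 1))
                    for p in report.steady_periods
                    if p.start_day < window[0]
                ]
                pre = [(a, b) for a, b in pre if b - a + 1 >= STEADY_MIN_DAYS]
                per_period = [
                    SteadyStatePeriod(
                        a,
                        b,
                        mean=float(series.loc[a:b].mean()),
                        minimum=float(series.loc[a:b].min()),
                        maximum=float(series.loc[a:b].max()),
                    )
                    for a, b in pre
                    if len(series.loc[a:b])
                ]
                if per_period:
                    try:
                        rec.amplitude_min, rec.amplitude_max = amplitude_range(
                            event.value, per_period, direction
                        )
                    except ValueError as exc:
                        report.warnings.append(f"{name} {window}: {exc}")
                thr = thresholds.by_indicator.get(name)
                if thr is not None and rec.amplitude_max is not None:
                    if thr >= 0:
                        rec.risk_flag = rec.amplitude_max >= thr
                    else:
                        rec.risk_flag = rec.amplitude_min <= thr
            report.records.append(rec)
    return report
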