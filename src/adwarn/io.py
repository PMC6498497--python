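"""Shared file formats: daily time-series CSV, schedules, parameter files.

The daily table is a tidy CSV with one row per day and a fixed column
dictionary; extra columns are preserved on read (and logged), missing
optional columns are allowed and reported.  Parameter files are flat
``key = value`` text with ``#`` comments, e.g.::

    # kinetics of the acetate-consuming archaea
    acetoclastic_methanogens.mu_max = 0.40
    ki_vfa = 315.0
"""

from __future__ import annotations

import dataclasses
import datetime as _dt
import logging
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .biomodel import GROUPS, GroupKinetics, KineticParams
from .schedules import OperationPhase, OperationSchedule

__all__ = [
    "ValidationError",
    "COLUMN_DICTIONARY",
    "read_timeseries",
    "write_timeseries",
    "read_schedule",
    "write_schedule",
    "load_kinetic_params",
    "save_kinetic_params",
    "default_params_path",
    "write_manifest",
]

log = logging.getLogger(__name__)


class ValidationError(ValueError):
    """A table or parameter file violates its contract."""


# column name -> (kind, required); kinds drive validation
COLUMN_DICTIONARY: dict[str, tuple[str, bool]] = {
    "day": ("day", True),
    "biogas_L": ("nonneg", False),
    "ch4_frac": ("fraction", False),
    "co2_frac": ("fraction", False),
    "h2_frac": ("fraction", False),
    "ch4_yield_L_per_gVS": ("nonneg", False),
    "ac_gL": ("nonneg", False),
    "pro_gL": ("nonneg", False),
    "bu_gL": ("nonneg", False),
    "vfa_gL": ("nonneg", False),
    "ph": ("free", False),
    "ta_mgCaCO3L": ("nonneg", False),
    "ia_mgCaCO3L": ("nonneg", False),
    "ba_mgCaCO3L": ("nonneg", False),
    "ts_pct": ("nonneg", False),
    "vs_pct": ("nonneg", False),
    # coupled indicators, when shipped precomputed
    "ch4_co2": ("nonneg", False),
    "ia_ba": ("nonneg", False),
    "ba_ta": ("nonneg", False),
    "vfa_ba": ("nonneg", False),
}


def read_timeseries(path: str | Path) -> pd.DataFrame:
    """Read and validate a daily series CSV.

    Raises :class:`ValidationError` with row-numbered messages on duplicate
    or non-increasing days, negative concentrations or out-of-range
    fractions.  Unknown columns are preserved and logged; absent optional
    columns are logged.
    """
    path = Path(path)
    df = pd.read_csv(path)
    if "day" not in df.columns:
        raise ValidationError(f"{path}: missing required column 'day'")
    day = df["day"].to_numpy()
    dup = pd.Series(day).duplicated()
    if dup.any():
        bad = int(np.where(dup)[0][0])
        raise ValidationError(f"{path}: duplicated day {day[bad]!r} at row {bad + 2}")
    if not np.all(np.diff(day) > 0):
        bad = int(np.where(np.diff(day) <= 0)[0][0]) + 1
        raise ValidationError(f"{path}: day not strictly increasing at row {bad + 2}")
    for col in df.columns:
        if col not in COLUMN_DICTIONARY:
            log.info("%s: unknown column %r preserved", path, col)
            continue
        kind, _ = COLUMN_DICTIONARY[col]
        vals = pd.to_numeric(df[col], errors="coerce")
        bad_num = df[col].notna() & vals.isna()
        if bad_num.any():
            row = int(np.where(bad_num)[0][0])
            raise ValidationError(f"{path}: malformed number in {col!r} at row {row + 2}")
        df[col] = vals
        finite = vals.dropna()
        if kind in ("nonneg", "day") and (finite < 0).any():
            row = int(np.where((vals < 0).fillna(False))[0][0])
            raise ValidationError(f"{path}: negative value in {col!r} at row {row + 2}")
        if kind == "fraction" and ((finite < 0) | (finite > 1)).any():
            row = int(np.where(((vals < 0) | (vals > 1)).fillna(False))[0][0])
            raise ValidationError(f"{path}: {col!r} outside [0, 1] at row {row + 2}")
    absent = [c for c, (_, req) in COLUMN_DICTIONARY.items() if not req and c not in df.columns]
    if absent:
        log.debug("%s: optional columns absent: %s", path, ", ".join(absent))
    return df


def write_timeseries(df: pd.DataFrame, path: str | Path) -> None:
    """Write a daily series CSV in the stable dictionary column order."""
    known = [c for c in COLUMN_DICTIONARY if c in df.columns]
    extra = [c for c in df.columns if c not in COLUMN_DICTIONARY]
    df[known + extra].to_csv(path, index=False)


_SCHEDULE_COLS = ["label", "start_day", "end_day", "feed_ts_percent", "hrt_days", "olr_stated", "mode"]


def read_schedule(path: str | Path, name: str | None = None) -> OperationSchedule:
    df = pd.read_csv(path)
    missing = set(_SCHEDULE_COLS) - set(df.columns)
    if missing:
        raise ValidationError(f"{path}: schedule missing columns {sorted(missing)}")
    phases = tuple(
        OperationPhase(
            label=str(r.label),
            start_day=int(r.start_day),
            end_day=int(r.end_day),
            feed_ts_percent=float(r.feed_ts_percent),
            hrt_days=float(r.hrt_days),
            olr_stated=float(r.olr_stated),
            mode=str(r.mode),
        )
        for r in df.itertuples()
    )
    return OperationSchedule(name=name or Path(path).stem, phases=phases)


def write_schedule(schedule: OperationSchedule, path: str | Path) -> None:
    pd.DataFrame(
        [{c: getattr(ph, c) for c in _SCHEDULE_COLS} for ph in schedule]
    ).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# kinetic parameter files
# ---------------------------------------------------------------------------

_SCALAR_FIELDS = {
    f.name
    for f in dataclasses.fields(KineticParams)
    if f.name not in ("groups", "gas_reference", "vfa_inhibitor_free_acid_only")
}
_GROUP_FIELDS = [f.name for f in dataclasses.fields(GroupKinetics)]


def default_params_path() -> Path:
    return Path(str(resources.files("adwarn").joinpath("data/default_params.txt")))


def load_kinetic_params(path: str | Path) -> KineticParams:
    """Parse a flat key=value parameter file into :class:`KineticParams`."""
    raw: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValidationError(f"{path}:{lineno}: expected 'key = value'")
        key, value = (part.strip() for part in line.split("=", 1))
        raw[key] = value
    groups: dict[str, dict[str, float]] = {g: {} for g in GROUPS}
    scalars: dict[str, object] = {}
    for key, value in raw.items():
        if "." in key:
            group, attr = key.split(".", 1)
            if group not in groups or attr not in _GROUP_FIELDS:
                raise ValidationError(f"{path}: unknown parameter {key!r}")
            groups[group][attr] = float(value)
        elif key in _SCALAR_FIELDS:
            scalars[key] = float(value)
        elif key == "gas_reference":
            scalars[key] = value
        elif key == "vfa_inhibitor_free_acid_only":
            scalars[key] = value.lower() in ("1", "true", "yes")
        else:
            raise ValidationError(f"{path}: unknown parameter {key!r}")
    for g, attrs in groups.items():
        missing = set(_GROUP_FIELDS) - set(attrs)
        if missing:
            raise ValidationError(f"{path}: group {g!r} missing {sorted(missing)}")
    return KineticParams(
        groups={g: GroupKinetics(**attrs) for g, attrs in groups.items()}, **scalars
    )


def save_kinetic_params(params: KineticParams, path: str | Path) -> None:
    lines = ["# adwarn kinetic parameter file (flat key = value)"]
    for g in GROUPS:
        gk = params.groups[g]
        for f in _GROUP_FIELDS:
            lines.append(f"{g}.{f} = {getattr(gk, f)!r}")
    for name in sorted(_SCALAR_FIELDS):
        lines.append(f"{name} = {getattr(params, name)!r}")
    lines.append(f"gas_reference = {params.gas_reference}")
    lines.append(f"vfa_inhibitor_free_acid_only = {params.vfa_inhibitor_free_acid_only}")
    Path(path).write_text("\n".join(lines) + "\n")


def write_manifest(path: str | Path, **entries) -> None:
    """Key: value run manifest (inputs, seeds, version) for reproducibility."""
    from . import __version__

    lines = [
        f"timestamp: {_dt.datetime.now().isoformat(timespec='seconds')}",
        f"adwarn_version: {__version__}",
    ]
    lines += [f"{k}: {v}" for k, v in entries.items()]
    Path(path).write_text("\n".join(lines) + "\n")
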