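"""Staged feeding plans for CSTR operation.

A schedule is a list of contiguous phases, each with a stated organic
loading rate (OLR, g VS/(L day)), a hydraulic retention time (HRT, days)
and a feed total-solids concentration.  Day ranges are stored inclusive on
both ends, exactly as operating tables print them (0-25, 26-50, ...).

The simulator feeds by the *stated* OLR on a VS basis, not by recomputing
the load from feed TS and HRT: OLR is the controlled variable of the
experiments this package emulates, and the TS/HRT arithmetic in published
operating tables does not always reproduce it exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

__all__ = ["PhaseMode", "OperationPhase", "OperationSchedule"]

PhaseMode = str
_MODES = {"replacement", "full_load", "gradual_overload", "sudden_overload", "recovery"}


@dataclass(frozen=True)
class OperationPhase:
    label: str
    start_day: int
    end_day: int  # inclusive
    feed_ts_percent: float  # % of fresh mass
    hrt_days: float
    olr_stated: float  # g VS/(L day)
    mode: PhaseMode

    def __post_init__(self) -> None:
        if self.start_day > self.end_day:
            raise ValueError(f"phase {self.label!r}: start_day > end_day")
        if self.mode != "recovery" and self.hrt_days <= 0:
            raise ValueError(f"phase {self.label!r}: hrt_days must be > 0")
        if self.olr_stated < 0:
            raise ValueError(f"phase {self.label!r}: olr_stated must be >= 0")
        if self.mode not in _MODES:
            raise ValueError(f"phase {self.label!r}: unknown mode {self.mode!r}")

    @property
    def n_days(self) -> int:
        return self.end_day - self.start_day + 1

    def contains(self, day: float) -> bool:
        # day d covers the interval [d, d+1), so the phase spans
        # [start_day, end_day + 1)
        return self.start_day <= day < self.end_day + 1


@dataclass(frozen=True)
class OperationSchedule:
    name: str
    phases: tuple[OperationPhase, ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        for prev, nxt in zip(self.phases, self.phases[1:]):
            if nxt.start_day != prev.end_day + 1:
                raise ValueError(
                    f"schedule {self.name!r}: phases {prev.label!r} and "
                    f"{nxt.label!r} are not contiguous"
                )

    def __iter__(self) -> Iterator[OperationPhase]:
        return iter(self.phases)

    @property
    def start_day(self) -> int:
        return self.phases[0].start_day

    @property
    def end_day(self) -> int:
        return self.phases[-1].end_day

    def phase_at(self, day: float) -> OperationPhase:
        for ph in self.phases:
            if ph.contains(day):
                return ph
        raise ValueError(f"day {day} outside schedule {self.name!r}")

    def windows(self, mode: PhaseMode) -> list[tuple[int, int]]:
        """Merged inclusive day windows of all phases with the given mode."""
        out: list[tuple[int, int]] = []
        for ph in self.phases:
            if ph.mode != mode:
                continue
            if out and ph.start_day == out[-1][1] + 1:
                out[-1] = (out[-1][0], ph.end_day)
            else:
                out.append((ph.start_day, ph.end_day))
        return out
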