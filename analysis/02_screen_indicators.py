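#!/usr/bin/env python
"""Screen the packaged overload fixtures for early-warning events.

Builds the three engineered overload datasets (R1 gradual, R1 sudden, R2
gradual), runs the RSD-based screening pipeline on each, and writes the
per-indicator reports (abrupt-change day, warning time, amplitude range,
risk flags) to results/.  The screening is also run in 'simulated' mode on
the kinetic-model output of script 01 when present.
"""

from pathlib import Path

import pandas as pd

from adwarn.indicators import indicators_from_measurements, screen
from adwarn.io import read_timeseries
from adwarn.synthetic import (
    build_schedules,
    make_overload_fixture,
    preset_r1_gradual,
    preset_r1_sudden,
    preset_r2_gradual,
)

RESULTS = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    RESULTS.mkdir(exist_ok=True)
    schedules = build_schedules()
    for name, preset in (
        ("r1_gradual", preset_r1_gradual()),
        ("r1_sudden", preset_r1_sudden()),
        ("r2_gradual", preset_r2_gradual()),
    ):
        frame = make_overload_fixture(preset)
        report = screen(frame, schedules[preset.schedule_label], mode="experimental")
        report.to_frame().to_csv(RESULTS / f"screening_{name}.csv", index=False)
        print(f"=== {name} ===")
        print(report.summary())
        print()

    sim_path = RESULTS / "sim_r1.csv"
    if sim_path.exists():
        frame = indicators_from_measurements(read_timeseries(sim_path))
        report = screen(frame, schedules["R1"], mode="simulated")
        report.to_frame().to_csv(RESULTS / "screening_sim_r1.csv", index=False)
        print("=== simulated R1 (kinetic model output) ===")
        print(report.summary())


if __name__ == "__main__":
    main()
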