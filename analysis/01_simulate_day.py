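#!/usr/bin/env python
"""Simulate a measurement-day excerpt and write its signal files.

Generates a working-day excerpt (default 30 min of work with 12 scripted
overload epochs: two-muscle episodes at 1.5x the reference-lift threshold,
some under 60 degree forward flexion), the complete calibration protocol
and sync landmarks, then writes the four streams, annotations and the
ground-truth epoch table under results/day/.  The on-disk demo is kept
short so its text files stay small; the full 2-hour condition is exercised
in memory by the test suite and scripts/acceptance.py.
"""

import sys
from pathlib import Path

import numpy as np

from ergoload.pipeline import write_day
from ergoload.simulate import DayScenario, default_event_schedule, generate_day

OUT = Path(__file__).resolve().parent.parent / "results" / "day"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1
WORK_S = 1800.0


def main() -> None:
    scenario = DayScenario(
        duration_s=WORK_S,
        seed=SEED,
        events=default_event_schedule(12, WORK_S, intensity=1.5,
                                      rng=np.random.default_rng(SEED + 1)),
    )
    day = generate_day(scenario)
    write_day(day, OUT, fmt="%.6g")
    gt = day.ground_truth
    print(f"wrote {OUT}")
    print(f"work interval: {day.work_interval[0]:.0f}-{day.work_interval[1]:.0f} s on the EMG clock")
    print(f"ground truth: {gt.event_ref100.sum()} ref100 epochs, "
          f"{gt.event_ref150.sum()} ref150, {gt.event_mvc50.sum()} mvc50")
    print(f"true steps during work: {day.true_steps}")


if __name__ == "__main__":
    main()
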