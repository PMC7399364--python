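"""Feature-learnability time-series from a rolling 60 ms window.

Trials are synthesized with 1.1 s of pre-stimulus signal and at least
4.1 s post-onset so every window fits; the window advances in 200 ms
steps from 200 ms before stimulus onset to 4 s after (a coarse rendering
of the full 10 ms-step schedule), for all 16 classes and for the
tactile-only / proprioceptive-only restrictions (chance 6.25% vs 12.5%).
Writes results/rolling_learnability.csv.
"""

import sys
import time
from pathlib import Path

import pandas as pd

from dcnlearn import experiments as ex
from dcnlearn import features as ft
from dcnlearn import synthgen as sg

SEED = 1729
ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    schedule = sg.TrialSchedule(trials_per_set=5, sets=2)
    config = sg.GeneratorConfig.desk(
        schedule=schedule, pre_onset_s=1.1, min_post_onset_s=4.1
    )
    subset = ["hf_spike_count"]
    t0 = time.time()
    prefiltered = {
        a: ft.prefilter_dataset(sg.iter_animal_trials(config, a, SEED), subset)
        for a in range(2)
    }
    print(f"synthesized + filtered 2 animals ({time.time() - t0:.0f} s)")

    starts = ex.rolling_schedule(step_ms=200.0, include_baseline_sample=True)
    rows = []
    for restriction in ("all", "tactile", "proprio"):
        t0 = time.time()
        curve = ex.rolling_learnability(
            prefiltered, subset, window_length_ms=60.0, schedule=starts,
            class_restriction=restriction, seed=SEED, n_repeats=3,
        )
        chance = 6.25 if restriction == "all" else 12.5
        for c, m, s in zip(curve.abscissa_ms, curve.mean_pct, curve.sem_pct):
            rows.append(
                {"restriction": restriction, "window_center_ms": c,
                 "mean_pct": round(m, 2), "sem_pct": round(s, 2),
                 "chance_pct": chance}
            )
        peak = max(zip(curve.mean_pct, curve.abscissa_ms))
        print(f"{restriction:8s}: peak {peak[0]:.1f} % at {peak[1]:.0f} ms "
              f"(chance {chance} %, {time.time() - t0:.0f} s)")
    pd.DataFrame(rows).to_csv(ROOT / "results" / "rolling_learnability.csv", index=False)


if __name__ == "__main__":
    sys.exit(main())
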