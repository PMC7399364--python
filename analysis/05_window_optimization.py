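"""Learnability as a function of window length, and the optimal short
window by changepoint detection.

Sweeps onset-aligned windows (20–150 ms by 10 ms, plus 250, 500, 1000 ms)
for the four HF features, finds each curve's most abrupt change in mean,
averages the changepoint locations and rounds to the nearest tested
length. Writes results/window_sweep.csv.
"""

import sys
import time
from pathlib import Path

import pandas as pd

from dcnlearn import experiments as ex
from dcnlearn import features as ft
from dcnlearn import io as dio
from dcnlearn import learnability as ln

SEED = 6021
ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    cohort_dir = ROOT / "scratch" / "cohort"
    if not cohort_dir.exists():
        raise SystemExit("run analysis/01_generate_cohort.py first")
    cohort = dio.read_dataset(cohort_dir)
    subset = list(ft.HF_FEATURES)
    prefiltered = {
        ds.animal_id: ft.prefilter_dataset(ds, subset) for ds in cohort
    }

    t0 = time.time()
    rows = []
    curves = []
    for feature in subset:
        curve = ex.window_sweep(
            prefiltered, [feature], ex.DEFAULT_WINDOW_GRID, seed=SEED, n_repeats=3
        )
        curves.append(curve)
        for length, m, s in zip(curve.abscissa_ms, curve.mean_pct, curve.sem_pct):
            rows.append(
                {"feature": feature, "window_ms": length,
                 "mean_pct": round(m, 2), "sem_pct": round(s, 2)}
            )
        print(f"{feature}: {curve.mean_pct[0]:.1f} % @20 ms -> "
              f"{curve.mean_pct[-1]:.1f} % @1000 ms")

    optimal = ex.optimal_window(curves, ex.DEFAULT_WINDOW_GRID)
    pd.DataFrame(rows).to_csv(ROOT / "results" / "window_sweep.csv", index=False)
    print(f"optimal short window: {optimal:.0f} ms ({time.time() - t0:.0f} s)")


if __name__ == "__main__":
    sys.exit(main())
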