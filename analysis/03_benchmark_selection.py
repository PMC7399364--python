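"""Select the benchmark feature set with the adapted sequential forward
floating search.

Each round adds the next-best unused feature from each of the four
categories (per the ranking from 02), then tries single-feature removals.
The benchmark is the evaluated set with the highest mean learnability.
Writes results/benchmark_selection.csv (one row per selection step).
"""

import importlib.util
import sys
import time
from pathlib import Path

import pandas as pd

from dcnlearn import experiments as ex
from dcnlearn import features as ft

SEED = 2718
ROOT = Path(__file__).resolve().parent.parent

spec = importlib.util.spec_from_file_location(
    "feature_learnability", Path(__file__).parent / "02_feature_learnability.py"
)
_mod = importlib.util.module_from_spec(spec)
spec.loader.exec_module(_mod)
load_tables = _mod.load_tables


def main() -> None:
    tables = load_tables()
    ranking = pd.read_csv(ROOT / "results" / "feature_ranking.csv")
    if ranking.empty:
        raise SystemExit("run analysis/02_feature_learnability.py first")
    ranked_by_cat = {
        cat: [f for f in ranking["feature"] if f in fs]
        for cat, fs in ft.FEATURE_CATEGORIES.items()
    }
    t0 = time.time()
    trace = ex.adapted_sffs(tables, ranked_by_cat, seed=SEED, n_repeats=5)
    rows = [
        {
            "step": i + 1,
            "action": r["action"],
            "n_features": len(r["features"]),
            "mean_pct": round(r["mean"], 2),
            "sem_pct": round(r["sem"], 2),
            "features": ";".join(r["features"]),
        }
        for i, r in enumerate(trace.rounds)
    ]
    pd.DataFrame(rows).to_csv(ROOT / "results" / "benchmark_selection.csv", index=False)
    print(f"benchmark: {len(trace.benchmark_set)} features, "
          f"{trace.benchmark_mean:.1f} ± {trace.benchmark_sem:.1f} % "
          f"({time.time() - t0:.0f} s)")
    print("benchmark set:", ", ".join(sorted(trace.benchmark_set)))


if __name__ == "__main__":
    sys.exit(main())
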