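"""Rank all 22 signal features by individual feature-learnability.

For each feature, the standardized network sees only that feature's seven
electrode values (WIA protocol, 5 repeats per animal over the 1000 ms
window). Features are ranked by mean learnability, ties by SEM. Writes
results/feature_ranking.csv.
"""

import sys
import time
from pathlib import Path

import pandas as pd

from dcnlearn import features as ft
from dcnlearn import learnability as ln

SEED = 314
ROOT = Path(__file__).resolve().parent.parent


def load_tables() -> dict:
    path = ROOT / "scratch" / "features_1000ms.csv"
    if not path.exists():
        raise SystemExit("run analysis/01_generate_cohort.py first")
    combined = pd.read_csv(path)
    return {a: t.reset_index(drop=True) for a, t in combined.groupby("animal")}


def main() -> None:
    tables = load_tables()
    results = []
    t0 = time.time()
    for feature in ft.ALL_FEATURES:
        res = ln.wia_learnability(tables, [feature], n_repeats=5, seed=SEED)
        results.append(res)
        print(f"{feature:28s} {res.mean_pct:5.1f} ± {res.sem_pct:4.1f} %")
    ranked = ln.rank_features(results)
    by_name = {r.feature_subset[0]: r for r in results}
    cat_of = {f: c for c, fs in ft.FEATURE_CATEGORIES.items() for f in fs}
    out = pd.DataFrame(
        {
            "rank": range(1, len(ranked) + 1),
            "feature": ranked,
            "category": [cat_of[f] for f in ranked],
            "mean_pct": [round(by_name[f].mean_pct, 2) for f in ranked],
            "sem_pct": [round(by_name[f].sem_pct, 2) for f in ranked],
        }
    )
    out.to_csv(ROOT / "results" / "feature_ranking.csv", index=False)
    print(f"\ntop feature: {ranked[0]} "
          f"({by_name[ranked[0]].mean_pct:.1f} %); done in {time.time() - t0:.0f} s")


if __name__ == "__main__":
    sys.exit(main())
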