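"""Compare within-animal (WIA) and cross-animal (LOO) learnability.

Uses the benchmark feature set from 03 (falling back to the four HF
features) on the cohort's 1000 ms tables. The LOO deficit measures how
much of the decodable structure is animal-specific. Writes
results/generalization.csv.
"""

import importlib.util
import sys
from pathlib import Path

import pandas as pd

from dcnlearn import features as ft
from dcnlearn import learnability as ln

SEED = 1618
ROOT = Path(__file__).resolve().parent.parent

spec = importlib.util.spec_from_file_location(
    "feature_learnability", Path(__file__).parent / "02_feature_learnability.py"
)
_mod = importlib.util.module_from_spec(spec)
spec.loader.exec_module(_mod)
load_tables = _mod.load_tables


def benchmark_features() -> list:
    path = ROOT / "results" / "benchmark_selection.csv"
    if path.exists():
        best = pd.read_csv(path).sort_values("mean_pct").iloc[-1]
        return best["features"].split(";")
    return list(ft.HF_FEATURES)


def main() -> None:
    tables = load_tables()
    subset = benchmark_features()
    rows = []
    for name, fs in [("benchmark", subset), ("hf_top2", ["hf_spike_amplitude", "hf_spike_count"])]:
        wia = ln.wia_learnability(tables, fs, n_repeats=5, seed=SEED)
        loo = ln.loo_learnability(tables, fs, seed=SEED)
        rows.append(
            {
                "feature_set": name,
                "n_features": len(fs),
                "wia_mean_pct": round(wia.mean_pct, 2),
                "wia_sem_pct": round(wia.sem_pct, 2),
                "loo_mean_pct": round(loo.mean_pct, 2),
                "loo_sem_pct": round(loo.sem_pct, 2),
                "loo_deficit_pct": round(wia.mean_pct - loo.mean_pct, 2),
            }
        )
        print(f"{name}: WIA {wia.mean_pct:.1f} ± {wia.sem_pct:.1f} %, "
              f"LOO {loo.mean_pct:.1f} ± {loo.sem_pct:.1f} %")
    pd.DataFrame(rows).to_csv(ROOT / "results" / "generalization.csv", index=False)


if __name__ == "__main__":
    sys.exit(main())
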