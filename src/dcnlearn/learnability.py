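"""Feature-learnability: decoding accuracy of the standardized classifier.

Feature-learnability of a feature set is the mean ± SEM of the diagonal of
an averaged row-normalized test confusion matrix:

* WIA (within individual animal): per animal, ``n_repeats`` seeded
  70/15/15 train/validate/test cycles are run on that animal's rows and
  their test confusions averaged into one representative matrix; the
  representative matrices are then averaged across animals.  Measures how
  decodable a feature is within a subject.
* LOO (leave-one-out): for each fold, the network is trained on the
  pooled rows of all other animals (70/30 train/validation) and tested on
  100% of the held-out animal.  Measures cross-subject generalization.

The SEM is computed across animals (sample SD / sqrt(n_animals)) of the
per-animal confusion-diagonal means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import classifier as clf
from .classifier import ClassifierSpec, ConfusionMatrix
from .features import ALL_FEATURES, META_COLUMNS, FeatureWindow, extract_feature_table
from .synthgen import (
    AnimalDataset,
    Limb,
    PROPRIO_TYPES,
    StimulusType,
    TACTILE_TYPES,
)

__all__ = [
    "LearnabilityResult",
    "DEFAULT_WINDOW",
    "RELEVANT_ELECTRODES",
    "as_feature_tables",
    "wia_learnability",
    "loo_learnability",
    "rank_features",
    "quantify_feature",
]

#: The long analysis window: the first 1000 ms after stimulus onset.
DEFAULT_WINDOW = FeatureWindow(0.0, 1000.0)

#: Anatomically relevant electrodes per limb (1-based electrode names):
#: forelimbs map to their side's lateral pair, hindlimbs to the midline.
RELEVANT_ELECTRODES: dict = {
    Limb.LEFT_FORE: (1, 2),
    Limb.RIGHT_FORE: (6, 7),
    Limb.LEFT_HIND: (3, 4, 5),
    Limb.RIGHT_HIND: (3, 4, 5),
}


@dataclass
class LearnabilityResult:
    mean_pct: float
    sem_pct: float
    per_animal_confusions: list
    grand_confusion: ConfusionMatrix
    feature_subset: tuple
    window: FeatureWindow | None
    protocol: str  # "WIA" | "LOO"
    n_repeats: int

    def __repr__(self) -> str:  # compact, for analysis logs
        return (
            f"LearnabilityResult({self.protocol}, {len(self.feature_subset)} features, "
            f"{self.mean_pct:.1f} ± {self.sem_pct:.1f} %)"
        )


def as_feature_tables(
    datasets,
    feature_subset: Sequence[str] | None = None,
    window: FeatureWindow | None = None,
) -> dict:
    """Normalize inputs to ``{animal_id: feature table}``.

    ``datasets`` may be a list of :class:`AnimalDataset` (features are
    extracted), a mapping ``{animal_id: DataFrame}``, or a list of
    pre-extracted DataFrames carrying an ``animal`` column.  When tables
    are supplied and ``feature_subset`` is given, the tables are restricted
    to those features' columns.
    """
    if window is None:
        window = DEFAULT_WINDOW
    if isinstance(datasets, Mapping):
        values = list(datasets.values())
        if values and isinstance(values[0], pd.DataFrame):
            tables = dict(datasets)
        else:
            # animal_id -> iterable of (Filtered)Trial
            return {
                aid: extract_feature_table(trials, window, feature_subset)
                for aid, trials in datasets.items()
            }
    elif datasets and isinstance(datasets[0], AnimalDataset):
        tables = {
            ds.animal_id: extract_feature_table(ds, window, feature_subset)
            for ds in datasets
        }
        return tables
    elif datasets and isinstance(datasets[0], pd.DataFrame):
        tables = {int(t["animal"].iloc[0]): t for t in datasets}
    else:
        raise ValueError("no datasets supplied")

    if feature_subset is not None:
        restricted = {}
        for aid, t in tables.items():
            keep = [c for c in t.columns if c in META_COLUMNS] + [
                c
                for c in t.columns
                if c not in META_COLUMNS and c.split("_", 1)[1] in feature_subset
            ]
            restricted[aid] = t[keep]
        tables = restricted
    return tables


def _aggregate(
    per_animal: list[ConfusionMatrix],
    labels: tuple,
    feature_subset,
    window,
    protocol: str,
    n_repeats: int,
) -> LearnabilityResult:
    grand = ConfusionMatrix(
        np.mean([c.matrix for c in per_animal], axis=0), labels
    )
    diag_means = np.array([c.diagonal_mean for c in per_animal])
    mean_pct = 100.0 * grand.diagonal_mean
    if len(per_animal) > 1:
        sem_pct = 100.0 * float(np.std(diag_means, ddof=1) / np.sqrt(len(diag_means)))
    else:
        warnings.warn("single animal: SEM across animals reported as 0", stacklevel=3)
        sem_pct = 0.0
    return LearnabilityResult(
        mean_pct=mean_pct,
        sem_pct=sem_pct,
        per_animal_confusions=per_animal,
        grand_confusion=grand,
        feature_subset=tuple(feature_subset) if feature_subset else tuple(),
        window=window,
        protocol=protocol,
        n_repeats=n_repeats,
    )


def _repeat_seeds(seed: int, n: int, salt: int) -> list[int]:
    ss = np.random.SeedSequence((int(seed), salt))
    return [int(s) for s in ss.generate_state(n) >> 1]  # keep < 2**31


def wia_learnability(
    datasets,
    feature_subset: Sequence[str] | None = None,
    window: FeatureWindow | None = None,
    n_repeats: int = 10,
    seed: int = 0,
    spec: ClassifierSpec | None = None,
) -> LearnabilityResult:
    """Within-individual-animal feature-learnability (mean ± SEM, %)."""
    tables = as_feature_tables(datasets, feature_subset, window)
    if len(tables) < 1:
        raise ValueError("WIA requires at least one animal")
    labels = None
    per_animal = []
    for k, (aid, table) in enumerate(sorted(tables.items())):
        if labels is None:
            labels = tuple(sorted(table["condition"].unique()))
        confusions = []
        for r, s in enumerate(_repeat_seeds(seed, n_repeats, 0xB0 + k)):
            model = clf.train(table, spec, seed=s)
            if model.test_confusion is None:
                raise ValueError("WIA needs a nonzero test fraction in the split")
            confusions.append(model.test_confusion.matrix)
        per_animal.append(ConfusionMatrix(np.mean(confusions, axis=0), labels))
    return _aggregate(per_animal, labels, feature_subset, window, "WIA", n_repeats)


def loo_learnability(
    datasets,
    feature_subset: Sequence[str] | None = None,
    window: FeatureWindow | None = None,
    seed: int = 0,
    spec: ClassifierSpec | None = None,
) -> LearnabilityResult:
    """Leave-one-animal-out feature-learnability (mean ± SEM, %).

    Each fold trains on the pooled rows of the other animals with a 70/30
    train/validation split and tests on every row of the held-out animal.
    """
    tables = as_feature_tables(datasets, feature_subset, window)
    if len(tables) < 2:
        raise ValueError("LOO requires at least two animals")
    if spec is None:
        spec = ClassifierSpec()
    fold_spec = replace(spec, split=(0.70, 0.30, 0.0))
    animal_ids = sorted(tables)
    labels = tuple(
        sorted(pd.concat([t["condition"] for t in tables.values()]).unique())
    )
    per_fold = []
    for k, held_out in enumerate(animal_ids):
        pooled = pd.concat(
            [tables[a] for a in animal_ids if a != held_out], ignore_index=True
        )
        s = _repeat_seeds(seed, len(animal_ids), 0x100)[k]
        model = clf.train(pooled, fold_spec, seed=s)
        test = tables[held_out]
        _, pred = clf.predict(model, test)
        per_fold.append(
            clf.confusion_from_predictions(test["condition"].to_numpy(), pred, labels)
        )
    return _aggregate(per_fold, labels, feature_subset, window, "LOO", 1)


def rank_features(results: Sequence[LearnabilityResult]) -> list[str]:
    """Order features by mean learnability (desc), ties by SEM (asc), then
    by the declared battery order."""
    names = []
    for r in results:
        if len(r.feature_subset) != 1:
            raise ValueError("rank_features expects single-feature results")
        names.append(r.feature_subset[0])
    if len(set(names)) != len(names):
        raise ValueError("duplicate feature names in results")
    order = {f: i for i, f in enumerate(ALL_FEATURES)}
    ranked = sorted(
        zip(names, results),
        key=lambda nr: (-nr[1].mean_pct, nr[1].sem_pct, order.get(nr[0], len(order))),
    )
    return [n for n, _ in ranked]


@dataclass
class FeatureQuantification:
    """Per-condition feature magnitudes on anatomically relevant electrodes."""

    feature: str
    per_type_mean: dict  # StimulusType -> mean
    per_type_sem: dict
    unit_values: pd.DataFrame  # one row per (animal, limb, electrode, type)
    tests: dict  # named t-test results: {"name": (statistic, pvalue)}


def quantify_feature(
    datasets,
    feature: str = "hf_spike_count",
    window: FeatureWindow | None = None,
    spike_threshold=None,
) -> FeatureQuantification:
    """Condition means ± SEM of ``feature`` from relevant electrodes.

    For each (animal, limb, electrode, stimulus type) unit the feature is
    averaged over trials, taking only the limb's anatomically relevant
    electrodes.  Pairwise comparisons: paired t-tests within stimulus
    category (dowel vs brush, flexion vs extension, paired by unit) and a
    two-sample t-test between tactile and proprioceptive categories.
    """
    if feature not in ALL_FEATURES:
        raise ValueError(f"unknown feature {feature!r}")
    if window is None:
        window = DEFAULT_WINDOW
    if spike_threshold is not None:
        if not (datasets and isinstance(datasets[0], AnimalDataset)):
            raise ValueError("spike_threshold override requires raw datasets")
        tables = {
            ds.animal_id: extract_feature_table(
                ds, window, [feature], spike_threshold=spike_threshold
            )
            for ds in datasets
        }
    else:
        tables = as_feature_tables(datasets, [feature], window)

    rows = []
    for aid, table in tables.items():
        stim = table["condition"].map(lambda c: c.split(":")[0])
        limb = table["condition"].map(lambda c: c.split(":")[1])
        for limb_enum, electrodes in RELEVANT_ELECTRODES.items():
            sel = table[limb == limb_enum.value]
            if sel.empty:
                continue
            for st in StimulusType:
                sub = sel[stim[sel.index] == st.value]
                if sub.empty:
                    continue
                for e in electrodes:
                    col = f"e{e}_{feature}"
                    rows.append(
                        {
                            "animal": aid,
                            "limb": limb_enum.value,
                            "electrode": e,
                            "stimulus_type": st.value,
                            "value": float(sub[col].mean()),
                        }
                    )
    units = pd.DataFrame(rows)
    if units.empty:
        raise ValueError("no trials matched the relevant-electrode mapping")

    per_type_mean: dict = {}
    per_type_sem: dict = {}
    for st in StimulusType:
        v = units.loc[units["stimulus_type"] == st.value, "value"].to_numpy()
        if len(v):
            per_type_mean[st] = float(np.mean(v))
            per_type_sem[st] = float(stats.sem(v)) if len(v) > 1 else 0.0

    tests: dict = {}

    def paired(a: StimulusType, b: StimulusType, name: str) -> None:
        pa = units[units["stimulus_type"] == a.value].set_index(
            ["animal", "limb", "electrode"]
        )["value"]
        pb = units[units["stimulus_type"] == b.value].set_index(
            ["animal", "limb", "electrode"]
        )["value"]
        common = pa.index.intersection(pb.index)
        if len(common) >= 2:
            res = stats.ttest_rel(pa.loc[common], pb.loc[common])
            tests[name] = (float(res.statistic), float(res.pvalue))

    paired(StimulusType.DOWEL, StimulusType.BRUSH, "dowel_vs_brush")
    paired(StimulusType.FLEXION, StimulusType.EXTENSION, "flexion_vs_extension")

    tac = units[units["stimulus_type"].isin([s.value for s in TACTILE_TYPES])]["value"]
    pro = units[units["stimulus_type"].isin([s.value for s in PROPRIO_TYPES])]["value"]
    if len(tac) >= 2 and len(pro) >= 2:
        res = stats.ttest_ind(pro, tac)
        tests["proprioceptive_vs_tactile"] = (float(res.statistic), float(res.pvalue))

    return FeatureQuantification(feature, per_type_mean, per_type_sem, units, tests)
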