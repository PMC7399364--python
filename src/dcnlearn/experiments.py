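"""Benchmark feature selection, window optimization and rolling decoding.

* :func:`adapted_sffs` — a sequential forward floating search adapted to
  the four feature categories: each round adds the next-best unused
  feature *from each category* (up to four per round), then a backward
  pass removes any feature whose removal improves mean learnability.  The
  benchmark is the evaluated set with maximal mean (ties favor the
  smaller set).
* :func:`window_sweep` — learnability of a feature set for onset-aligned
  windows of increasing length (default grid 20–150 ms by 10 ms, plus
  250, 500 and 1000 ms → 17 lengths).
* :func:`optimal_window` — the most abrupt change in each
  learnability-vs-window-length curve, found as the single change-in-mean
  point minimizing total squared deviation from segment means (exhaustive
  split search); changepoint locations are averaged across curves and
  rounded to the nearest tested length.
* :func:`rolling_learnability` — learnability time-series from a short
  window advanced every 10 ms (default: starts −200…+4000 ms → 421
  windows, plus an optional extra sample at −1000 ms), optionally
  restricted to tactile-only or proprioceptive-only classes (K = 8,
  chance 12.5%).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from .classifier import ClassifierSpec
from .features import FeatureWindow
from .learnability import as_feature_tables, wia_learnability
from .synthgen import PROPRIO_TYPES, TACTILE_TYPES

__all__ = [
    "SelectionTrace",
    "LearnabilityCurve",
    "DEFAULT_WINDOW_GRID",
    "adapted_sffs",
    "window_sweep",
    "find_changepoint",
    "optimal_window",
    "rolling_schedule",
    "rolling_learnability",
]

#: Window lengths (ms) of the sweep: 20–150 by 10, then 250, 500, 1000.
DEFAULT_WINDOW_GRID: tuple = tuple(range(20, 151, 10)) + (250, 500, 1000)


@dataclass
class SelectionTrace:
    """Round-by-round record of the adapted SFFS."""

    rounds: list = field(default_factory=list)  # dicts: action, features, mean, sem
    benchmark_set: tuple = ()
    benchmark_mean: float = float("nan")
    benchmark_sem: float = float("nan")

    def record(self, action: str, features: Sequence[str], mean: float, sem: float) -> None:
        self.rounds.append(
            {"action": action, "features": tuple(features), "mean": mean, "sem": sem}
        )


@dataclass
class LearnabilityCurve:
    """Learnability as a function of window length or window center (ms)."""

    abscissa_ms: np.ndarray
    mean_pct: np.ndarray
    sem_pct: np.ndarray
    feature_subset: tuple
    class_restriction: str = "all"
    label: str = ""

    def __post_init__(self) -> None:
        self.abscissa_ms = np.asarray(self.abscissa_ms, dtype=float)
        self.mean_pct = np.asarray(self.mean_pct, dtype=float)
        self.sem_pct = np.asarray(self.sem_pct, dtype=float)
        if np.any(np.diff(self.abscissa_ms) <= 0):
            raise ValueError("curve abscissa must be strictly increasing")


EvalFn = Callable[[Sequence[str]], tuple[float, float]]


def _default_eval(
    datasets, window: FeatureWindow, seed: int, n_repeats: int, spec: ClassifierSpec | None
) -> EvalFn:
    tables = as_feature_tables(datasets, None, window)

    def evaluate(subset: Sequence[str]) -> tuple[float, float]:
        res = wia_learnability(
            tables, subset, window, n_repeats=n_repeats, seed=seed, spec=spec
        )
        return res.mean_pct, res.sem_pct

    return evaluate


def adapted_sffs(
    datasets,
    ranked_features_by_category: Mapping[str, Sequence[str]],
    window: FeatureWindow | None = None,
    seed: int = 0,
    eval_fn: EvalFn | None = None,
    n_repeats: int = 10,
    spec: ClassifierSpec | None = None,
) -> SelectionTrace:
    """Category-grouped sequential forward floating feature selection.

    ``ranked_features_by_category`` maps each category to its features in
    learnability rank order.  Features removed in a backward pass are
    treated as consumed and do not re-enter the pool.  ``eval_fn`` maps a
    feature subset to (mean, sem) learnability; by default it runs WIA on
    ``datasets``.
    """
    if not ranked_features_by_category or not any(
        ranked_features_by_category.values()
    ):
        raise ValueError("empty feature rankings")
    if eval_fn is None:
        if window is None:
            from .learnability import DEFAULT_WINDOW

            window = DEFAULT_WINDOW
        eval_fn = _default_eval(datasets, window, seed, n_repeats, spec)

    queues = {c: list(fs) for c, fs in ranked_features_by_category.items() if fs}
    cache: dict = {}

    def evaluate(subset: Sequence[str]) -> tuple[float, float]:
        key = frozenset(subset)
        if key not in cache:
            cache[key] = eval_fn(tuple(subset))
        return cache[key]

    trace = SelectionTrace()
    current: list[str] = []
    best_set: tuple = ()
    best = (-np.inf, 0)  # (mean, -size) maximized; ties favor smaller sets

    def consider(subset: Sequence[str], mean: float, sem: float) -> None:
        nonlocal best, best_set
        key = (mean, -len(subset))
        if key > best:
            best = key
            best_set = tuple(subset)
            trace.benchmark_mean, trace.benchmark_sem = mean, sem

    while any(queues.values()):
        added = []
        for cat in queues:
            if queues[cat]:
                f = queues[cat].pop(0)
                current.append(f)
                added.append(f)
        mean, sem = evaluate(current)
        trace.record(f"add {'+'.join(added)}", current, mean, sem)
        consider(current, mean, sem)

        # Backward pass: drop any feature whose removal improves the mean.
        improved = True
        while improved and len(current) > 1:
            improved = False
            best_removal = None
            best_gain = (mean, 0.0)
            for f in list(current):
                candidate = [g for g in current if g != f]
                m, s = evaluate(candidate)
                if m > best_gain[0]:
                    best_gain = (m, s)
                    best_removal = f
            if best_removal is not None:
                current.remove(best_removal)
                mean, sem = best_gain
                trace.record(f"remove {best_removal}", current, mean, sem)
                consider(current, mean, sem)
                improved = True

    trace.benchmark_set = best_set
    return trace


def window_sweep(
    datasets,
    feature_subset: Sequence[str],
    window_lengths: Sequence[float] = DEFAULT_WINDOW_GRID,
    seed: int = 0,
    n_repeats: int = 10,
    spec: ClassifierSpec | None = None,
    eval_fn: Callable[[FeatureWindow], tuple[float, float]] | None = None,
) -> LearnabilityCurve:
    """Learnability per onset-aligned window length."""
    lengths = sorted(float(w) for w in window_lengths)
    if not lengths:
        raise ValueError("empty window-length grid")
    means, sems = [], []
    for length in lengths:
        w = FeatureWindow(0.0, length)
        if eval_fn is not None:
            m, s = eval_fn(w)
        else:
            res = wia_learnability(
                datasets, feature_subset, w, n_repeats=n_repeats, seed=seed, spec=spec
            )
            m, s = res.mean_pct, res.sem_pct
        means.append(m)
        sems.append(s)
    return LearnabilityCurve(
        np.array(lengths), np.array(means), np.array(sems), tuple(feature_subset)
    )


def find_changepoint(values: Sequence[float]) -> int | None:
    """Single change-in-mean point by exhaustive split search.

    Returns the index of the first point of the right segment minimizing
    the total squared deviation from the two segment means, or ``None``
    for a constant (zero-variance) series.
    """
    v = np.asarray(values, dtype=float)
    if len(v) < 2 or np.ptp(v) == 0:
        return None
    best_k, best_cost = None, np.inf
    for k in range(1, len(v)):
        left, right = v[:k], v[k:]
        cost = float(((left - left.mean()) ** 2).sum() + ((right - right.mean()) ** 2).sum())
        if cost < best_cost - 1e-12:
            best_cost, best_k = cost, k
    return best_k


def optimal_window(
    curves: Sequence[LearnabilityCurve],
    tested_lengths: Sequence[float] | None = None,
) -> float:
    """Average changepoint location across curves, rounded to the nearest
    tested window length (ties toward the shorter window).

    Constant curves carry no changepoint and are excluded with a warning;
    if every curve is constant this is an error.
    """
    if not curves:
        raise ValueError("no curves supplied")
    grid = curves[0].abscissa_ms
    for c in curves[1:]:
        if len(c.abscissa_ms) != len(grid) or np.any(c.abscissa_ms != grid):
            raise ValueError("curves must share one abscissa grid")
    if tested_lengths is None:
        tested_lengths = grid
    locations = []
    for c in curves:
        k = find_changepoint(c.mean_pct)
        if k is None:
            warnings.warn(
                f"curve {c.label or c.feature_subset} is constant: no changepoint",
                stacklevel=2,
            )
            continue
        locations.append(grid[k])
    if not locations:
        raise ValueError("no curve has a changepoint (all constant)")
    target = float(np.mean(locations))
    tested = sorted(float(t) for t in tested_lengths)
    return min(tested, key=lambda t: (abs(t - target), t))


def rolling_schedule(
    start_ms: float = -200.0,
    stop_ms: float = 4000.0,
    step_ms: float = 10.0,
    include_baseline_sample: bool = False,
    baseline_start_ms: float = -1000.0,
) -> list[float]:
    """Window start times of the rolling sweep (421 at the defaults).

    The optional baseline sample at −1000 ms is outside the regular
    10 ms grid and is prepended when requested.
    """
    starts = list(np.arange(start_ms, stop_ms + step_ms / 2.0, step_ms))
    if include_baseline_sample:
        starts = [baseline_start_ms] + starts
    return [float(s) for s in starts]


def rolling_learnability(
    datasets,
    feature_subset: Sequence[str],
    window_length_ms: float = 60.0,
    schedule: Sequence[float] | None = None,
    class_restriction: str = "all",
    seed: int = 0,
    n_repeats: int = 10,
    spec: ClassifierSpec | None = None,
    eval_fn: Callable[[FeatureWindow], tuple[float, float]] | None = None,
) -> LearnabilityCurve:
    """Learnability time-series from a short rolling window.

    ``class_restriction`` ∈ {"all", "tactile", "proprio"} restricts both
    inputs and outputs to the 8 tactile- or proprioception-dominated
    classes (chance level 100/K).  The curve abscissa is the window
    center.  Trials must span every scheduled window (synthesize with
    ``pre_onset_s`` / ``min_post_onset_s`` for pre-stimulus or long
    post-onset windows).
    """
    if schedule is None:
        schedule = rolling_schedule()
    if class_restriction not in ("all", "tactile", "proprio"):
        raise ValueError(f"unknown class restriction {class_restriction!r}")
    starts = sorted(float(s) for s in schedule)
    if not starts:
        raise ValueError("empty schedule")

    keep_types = None
    if class_restriction == "tactile":
        keep_types = {s.value for s in TACTILE_TYPES}
    elif class_restriction == "proprio":
        keep_types = {s.value for s in PROPRIO_TYPES}

    means, sems = [], []
    for start in starts:
        w = FeatureWindow(start, window_length_ms)
        if eval_fn is not None:
            m, s = eval_fn(w)
        else:
            tables = as_feature_tables(datasets, feature_subset, w)
            if keep_types is not None:
                tables = {
                    a: t[t["condition"].str.split(":").str[0].isin(keep_types)]
                    for a, t in tables.items()
                }
            res = wia_learnability(
                tables, feature_subset, w, n_repeats=n_repeats, seed=seed, spec=spec
            )
            m, s = res.mean_pct, res.sem_pct
        means.append(m)
        sems.append(s)
    centers = np.asarray(starts) + window_length_ms / 2.0
    return LearnabilityCurve(
        centers,
        np.array(means),
        np.array(sems),
        tuple(feature_subset),
        class_restriction,
    )
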