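"""Shared fixtures: small synthetic cohorts and feature tables.

Everything is generated at run time from seeds; session scope amortizes
the signal synthesis and filtering across tests.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from dcnlearn import features as ft
from dcnlearn import learnability as ln
from dcnlearn import synthgen as sg

MASTER_SEED = 20260928


@pytest.fixture(scope="session")
def desk_config() -> sg.GeneratorConfig:
    """Desk-scale generator: 10 kHz, full default statistics."""
    return sg.GeneratorConfig.desk()


@pytest.fixture(scope="session")
def small_schedule() -> sg.TrialSchedule:
    """Reduced schedule: 10 trials per condition (160 per animal)."""
    return sg.TrialSchedule(trials_per_set=5, sets=2)


@pytest.fixture(scope="session")
def small_cohort(small_schedule) -> list:
    """Two desk-scale animals, 160 trials each, default statistics."""
    config = sg.GeneratorConfig.desk(schedule=small_schedule)
    return [sg.generate_animal(config, a, MASTER_SEED) for a in range(2)]


@pytest.fixture(scope="session")
def small_tables(small_cohort) -> dict:
    """Full-battery 1000 ms feature tables of the small cohort."""
    return ln.as_feature_tables(small_cohort, None, ft.FeatureWindow(0.0, 1000.0))


def class_coded_table(
    animal_id: int,
    rng: np.random.Generator,
    n_per_class: int = 24,
    noise_sd: float = 0.5,
    separation: float = 10.0,
    codebook: np.ndarray | None = None,
    feature: str = "hf_spike_count",
) -> pd.DataFrame:
    """A synthetic feature table with class-coded electrode values.

    Each of the 16 conditions gets a 7-dimensional centroid (``codebook``
    row) separated by ``separation`` noise SDs; rows are centroid +
    Gaussian noise.  A shared codebook makes animals exchangeable; a
    per-animal codebook makes the code animal-specific (decodable within
    but not across animals).
    """
    labels = [c.label for c in sg.ALL_CONDITIONS]
    if codebook is None:
        codebook = rng.normal(0.0, separation * noise_sd, size=(len(labels), 7))
    rows = []
    cols = ft.feature_columns([feature])
    for k, lab in enumerate(labels):
        x = codebook[k] + rng.normal(0.0, noise_sd, size=(n_per_class, 7))
        for i in range(n_per_class):
            rows.append([animal_id, k * n_per_class + i, lab, 0.0, 1000.0, *x[i]])
    return pd.DataFrame(rows, columns=list(ft.META_COLUMNS) + cols)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(MASTER_SEED)
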