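"""On-disk dataset format, run configuration and serialization.

A cohort directory holds one subdirectory per animal::

    cohort/
      animal_000/
        manifest.json       # schema, seed, config, trial index
        trial_00000.f32     # raw little-endian float32, electrodes-major
        ...

The manifest records every trial's file, condition label, onset sample,
sampling rate and shape, so regeneration and round-tripping are
verifiable.  Run configurations serialize to YAML and round-trip
losslessly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classifier import ClassifierSpec
from .synthgen import (
    AnimalDataset,
    GeneratorConfig,
    Limb,
    StimulusCondition,
    StimulusType,
    Trial,
    TrialSchedule,
)

__all__ = [
    "SCHEMA_VERSION",
    "DatasetError",
    "MissingTrialFileError",
    "ShapeMismatchError",
    "UnknownSchemaError",
    "RunConfig",
    "write_dataset",
    "read_dataset",
    "config_to_dict",
    "config_from_dict",
]

SCHEMA_VERSION = 1


class DatasetError(ValueError):
    """Base class for on-disk dataset problems."""


class MissingTrialFileError(DatasetError):
    pass


class ShapeMismatchError(DatasetError):
    pass


class UnknownSchemaError(DatasetError):
    pass


def config_to_dict(config: GeneratorConfig) -> dict:
    d = dataclasses.asdict(config)
    d["electrode_gain"] = {
        limb.value: list(g) for limb, g in config.electrode_gain.items()
    }
    d["base_spike_amp_uV"] = {s.value: v for s, v in config.base_spike_amp_uV.items()}
    d["target_spike_count"] = {s.value: v for s, v in config.target_spike_count.items()}
    d["schedule"] = dataclasses.asdict(config.schedule)
    d["dowel_tau"] = list(config.dowel_tau)
    d["brush_tau"] = list(config.brush_tau)
    return d


def config_from_dict(d: dict) -> GeneratorConfig:
    d = dict(d)
    d["electrode_gain"] = {
        Limb(k): tuple(v) for k, v in d["electrode_gain"].items()
    }
    d["base_spike_amp_uV"] = {
        StimulusType(k): v for k, v in d["base_spike_amp_uV"].items()
    }
    d["target_spike_count"] = {
        StimulusType(k): v for k, v in d["target_spike_count"].items()
    }
    d["schedule"] = TrialSchedule(**d["schedule"])
    d["dowel_tau"] = tuple(d["dowel_tau"])
    d["brush_tau"] = tuple(d["brush_tau"])
    return GeneratorConfig(**d)


def _config_hash(config: GeneratorConfig) -> str:
    blob = json.dumps(config_to_dict(config), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def write_dataset(datasets: list[AnimalDataset], path) -> None:
    """Write a cohort: per-animal manifest + raw float32 trial files."""
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    for ds in datasets:
        adir = root / f"animal_{ds.animal_id:03d}"
        adir.mkdir(exist_ok=True)
        index = []
        for i, trial in enumerate(ds.trials):
            fname = f"trial_{i:05d}.f32"
            arr = np.asarray(trial.signal, dtype="<f4")
            arr.tofile(adir / fname)
            index.append(
                {
                    "file": fname,
                    "condition": trial.condition.label,
                    "onset_sample": int(trial.onset_sample),
                    "fs": float(trial.fs),
                    "n_electrodes": int(trial.signal.shape[0]),
                    "n_samples": int(trial.signal.shape[1]),
                    "trial_id": int(trial.trial_id),
                }
            )
        manifest = {
            "schema_version": SCHEMA_VERSION,
            "animal_id": int(ds.animal_id),
            "seed": int(ds.seed),
            "config": config_to_dict(ds.config),
            "config_hash": _config_hash(ds.config),
            "trials": index,
        }
        (adir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def read_dataset(path) -> list[AnimalDataset]:
    """Load a cohort written by :func:`write_dataset`.

    Raises :class:`UnknownSchemaError`, :class:`MissingTrialFileError` or
    :class:`ShapeMismatchError` for the corresponding defects.
    """
    root = Path(path)
    manifests = sorted(root.glob("animal_*/manifest.json"))
    if not manifests:
        raise DatasetError(f"no animal manifests under {root}")
    out = []
    for mpath in manifests:
        manifest = json.loads(mpath.read_text())
        if manifest.get("schema_version") != SCHEMA_VERSION:
            raise UnknownSchemaError(
                f"{mpath}: schema {manifest.get('schema_version')!r}, "
                f"expected {SCHEMA_VERSION}"
            )
        config = config_from_dict(manifest["config"])
        trials = []
        for entry in manifest["trials"]:
            fpath = mpath.parent / entry["file"]
            if not fpath.exists():
                raise MissingTrialFileError(f"missing trial file {fpath}")
            raw = np.fromfile(fpath, dtype="<f4")
            shape = (entry["n_electrodes"], entry["n_samples"])
            if raw.size != shape[0] * shape[1]:
                raise ShapeMismatchError(
                    f"{fpath}: {raw.size} values, expected {shape[0] * shape[1]}"
                )
            trials.append(
                Trial(
                    raw.reshape(shape).astype(float),
                    StimulusCondition.from_label(entry["condition"]),
                    entry["onset_sample"],
                    entry["fs"],
                    manifest["animal_id"],
                    entry["trial_id"],
                )
            )
        out.append(AnimalDataset(manifest["animal_id"], trials, config, manifest["seed"]))
    return out


@dataclass
class RunConfig:
    """Complete pipeline configuration; round-trips through YAML."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    classifier: ClassifierSpec = field(default_factory=ClassifierSpec)
    spike_threshold_multiplier: float = 3.5
    burst_threshold_multiplier: float = 2.0
    window_start_ms: float = 0.0
    window_len_ms: float = 1000.0
    window_grid_ms: tuple = tuple(range(20, 151, 10)) + (250, 500, 1000)
    n_animals: int = 2
    n_repeats: int = 10
    master_seed: int = 0
    out_dir: str = "results"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = config_to_dict(self.generator)
        d["classifier"] = dataclasses.asdict(self.classifier)
        d["classifier"]["split"] = list(self.classifier.split)
        d["window_grid_ms"] = list(self.window_grid_ms)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d["generator"] = config_from_dict(d["generator"])
        cspec = dict(d["classifier"])
        cspec["split"] = tuple(cspec["split"])
        d["classifier"] = ClassifierSpec(**cspec)
        d["window_grid_ms"] = tuple(d["window_grid_ms"])
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))
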