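"""Synthetic multi-electrode DCN-like evoked-potential generator.

Emulates surface recordings over the dorsal column nuclei during natural
mechanical stimulation of the four limbs with four stimulus types:

* ``dowel`` / ``brush`` — tactile-dominated presses; short spiking bursts at
  stimulus onset and offset (dowel sharp, peaking within 10 ms; brush
  ramped, peaking 20–30 ms after onset, occasionally with a second burst).
* ``flexion`` / ``extension`` — proprioception-dominated whole-limb
  movements; sustained activity over the on-phase peaking at the movement
  midpoint, plus a smaller burst during the return movement, with flexion
  recruiting more activity than extension.

Multiunit spiking is a binned Bernoulli realization of an inhomogeneous
rate profile (a censored Poisson process with a 0.5 ms resolution floor)
whose per-condition expected count over the first second after onset
equals ``target_spike_count`` exactly; each spike is a biphasic
(negative-leading)
extracellular template with amplitude jitter, mixed across the seven
electrodes by a limb-dependent gain matrix that encodes ipsilateral +
midline dominance, on top of additive broadband Gaussian noise with an
optional low-frequency component.

Spike amplitudes are calibrated so that ``base_spike_amp_uV`` is the
topographic prominence of the spike *after* the standard 550–3300 Hz
band-pass — i.e. the quantity the downstream spike detector measures.

The electrode layout follows the surface array convention: e1, e2 left of
midline; e3, e4, e5 midline; e6, e7 right of midline (1-based names,
0-based indices in code).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from functools import lru_cache
from typing import Iterator, Sequence

import numpy as np
from scipy import signal as sps

from . import sigproc

__all__ = [
    "StimulusType",
    "Limb",
    "StimulusCondition",
    "ALL_CONDITIONS",
    "TACTILE_TYPES",
    "PROPRIO_TYPES",
    "TrialSchedule",
    "GeneratorConfig",
    "Trial",
    "AnimalDataset",
    "response_rate_profile",
    "generate_trial",
    "generate_animal",
    "iter_animal_trials",
    "spike_template",
]


class StimulusType(str, Enum):
    DOWEL = "dowel"
    BRUSH = "brush"
    FLEXION = "flexion"
    EXTENSION = "extension"


class Limb(str, Enum):
    LEFT_FORE = "left_fore"
    RIGHT_FORE = "right_fore"
    LEFT_HIND = "left_hind"
    RIGHT_HIND = "right_hind"


TACTILE_TYPES = (StimulusType.DOWEL, StimulusType.BRUSH)
PROPRIO_TYPES = (StimulusType.FLEXION, StimulusType.EXTENSION)


@dataclass(frozen=True)
class StimulusCondition:
    """One of the 16 (stimulus type x limb) classes."""

    stimulus_type: StimulusType
    limb: Limb

    @property
    def is_tactile(self) -> bool:
        return self.stimulus_type in TACTILE_TYPES

    @property
    def is_proprioceptive(self) -> bool:
        return self.stimulus_type in PROPRIO_TYPES

    @property
    def label(self) -> str:
        return f"{self.stimulus_type.value}:{self.limb.value}"

    @classmethod
    def from_label(cls, label: str) -> "StimulusCondition":
        stim, limb = label.split(":")
        return cls(StimulusType(stim), Limb(limb))


ALL_CONDITIONS: tuple[StimulusCondition, ...] = tuple(
    StimulusCondition(s, l) for s in StimulusType for l in Limb
)


@dataclass(frozen=True)
class TrialSchedule:
    """Stimulus timing: 2.4 s phases, 10 sets of 10 trials per condition."""

    stimulus_on_s: float = 2.4
    rest_s: float = 2.4
    return_s: float = 2.4  # proprioceptive trials only
    trials_per_set: int = 10
    sets: int = 10
    inter_set_rest_s: float = 30.0  # metadata only; not synthesized

    def duration_s(self, condition: StimulusCondition) -> float:
        """Trial duration: tactile on+rest (4.8 s); proprioceptive
        on+return+rest (7.2 s)."""
        if condition.is_tactile:
            return self.stimulus_on_s + self.rest_s
        return self.stimulus_on_s + self.return_s + self.rest_s

    @property
    def trials_per_condition(self) -> int:
        return self.trials_per_set * self.sets

    def enumerate_trials(
        self, conditions: Sequence[StimulusCondition] = ALL_CONDITIONS
    ) -> list[tuple[StimulusCondition, int, int]]:
        """Ordered (condition, set index, trial-within-set index) triples."""
        return [
            (c, s, t)
            for c in conditions
            for s in range(self.sets)
            for t in range(self.trials_per_set)
        ]


def _default_electrode_gain() -> dict:
    # Rows encode ipsilateral + midline dominance: a limb's own-side
    # electrodes and the midline dominate the contralateral side.
    # Electrode order: e1, e2 (left) | e3, e4, e5 (midline) | e6, e7 (right).
    return {
        Limb.LEFT_FORE: (1.0, 1.0, 0.8, 0.8, 0.8, 0.2, 0.2),
        Limb.RIGHT_FORE: (0.2, 0.2, 0.8, 0.8, 0.8, 1.0, 1.0),
        Limb.LEFT_HIND: (0.4, 0.4, 1.0, 1.0, 1.0, 0.2, 0.2),
        Limb.RIGHT_HIND: (0.2, 0.2, 1.0, 1.0, 1.0, 0.4, 0.4),
    }


def _default_amp() -> dict:
    return {
        StimulusType.DOWEL: 30.2,
        StimulusType.BRUSH: 29.7,
        StimulusType.FLEXION: 32.4,
        StimulusType.EXTENSION: 31.1,
    }


def _default_count() -> dict:
    return {
        StimulusType.DOWEL: 41.6,
        StimulusType.BRUSH: 40.0,
        StimulusType.FLEXION: 129.1,
        StimulusType.EXTENSION: 87.9,
    }


@dataclass(frozen=True)
class GeneratorConfig:
    """Parameters of the synthetic cohort.

    ``target_spike_count`` is the expected number of spikes in the first
    1 s after stimulus onset on a unit-gain (anatomically relevant)
    electrode; ``base_spike_amp_uV`` is the mean post-filter spike
    prominence there.  ``pre_onset_s`` / ``min_post_onset_s`` extend the
    synthesized trace beyond the canonical trial span (needed for
    pre-stimulus baselines and long rolling-window sweeps); the canonical
    durations (4.8 / 7.2 s) hold at the defaults.
    """

    fs: float = 40000.0
    n_electrodes: int = 7
    schedule: TrialSchedule = field(default_factory=TrialSchedule)
    electrode_gain: dict = field(default_factory=_default_electrode_gain)
    spike_width_ms: float = 1.0
    spike_asymmetry: float = 0.45  # negative-lobe amplitude fraction
    spike_carrier_hz: float = 1400.0  # wavelet carrier, mid-band of 550-3300 Hz
    base_spike_amp_uV: dict = field(default_factory=_default_amp)
    target_spike_count: dict = field(default_factory=_default_count)
    amp_jitter_cv: float = 0.15
    noise_sd_uV: float = 3.0
    lf_noise_sd_uV: float = 2.0  # optional slow (<40 Hz) noise component
    animal_effect_sd: float = 0.1  # multiplicative log-normal jitter across animals
    residual_rate_hz: float = 0.0  # slowly-adapting baseline activity knob
    brush_double_burst_p: float = 0.3
    # Tactile kernel time constants (rise/decay, seconds)
    dowel_tau: tuple = (0.002, 0.020)
    brush_tau: tuple = (0.012, 0.045)
    offset_burst_scale: float = 0.8  # stimulus-removal burst relative to onset
    return_burst_scale: float = 0.6
    # Slowly-adapting activity during the tactile hold phase, relative to
    # the onset-burst peak rate.
    tactile_sustained_level: float = 0.015
    pre_onset_s: float = 0.0
    min_post_onset_s: float | None = None

    def __post_init__(self) -> None:
        scalars = {
            "fs": self.fs,
            "spike_width_ms": self.spike_width_ms,
            "amp_jitter_cv": self.amp_jitter_cv,
            "noise_sd_uV": self.noise_sd_uV,
            "lf_noise_sd_uV": self.lf_noise_sd_uV,
            "animal_effect_sd": self.animal_effect_sd,
            "residual_rate_hz": self.residual_rate_hz,
            "pre_onset_s": self.pre_onset_s,
        }
        for name, v in scalars.items():
            if v < 0:
                raise ValueError(f"{name} must be >= 0, got {v}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        for d in (self.base_spike_amp_uV, self.target_spike_count):
            for k, v in d.items():
                if v < 0:
                    raise ValueError(f"negative value {v} for {k}")
        if not 0.0 <= self.brush_double_burst_p <= 1.0:
            raise ValueError("brush_double_burst_p must be a probability")

    @classmethod
    def desk(cls, **overrides) -> "GeneratorConfig":
        """Desk-scale configuration: 10 kHz sampling (Nyquist 5 kHz still
        covers the 550–3300 Hz band and the 4 kHz spectral ceiling)."""
        overrides.setdefault("fs", 10000.0)
        return cls(**overrides)


@dataclass(frozen=True)
class Trial:
    """One labeled stimulus presentation: electrodes x samples trace (μV)."""

    signal: np.ndarray
    condition: StimulusCondition
    onset_sample: int
    fs: float
    animal_id: int
    trial_id: int

    def __post_init__(self) -> None:
        if not (0 <= self.onset_sample < self.signal.shape[1]):
            raise ValueError("onset_sample outside trial span")

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    def electrode(self, index: int) -> sigproc.TimeSeries:
        """Single-electrode trace as a TimeSeries (0-based index)."""
        return sigproc.TimeSeries(self.signal[index], self.fs)


@dataclass
class AnimalDataset:
    """All trials of one synthetic animal; bit-identical under its seed."""

    animal_id: int
    trials: list
    config: GeneratorConfig
    seed: int

    def conditions(self) -> set:
        return {t.condition for t in self.trials}


# ---------------------------------------------------------------------------
# Firing-rate profiles
# ---------------------------------------------------------------------------


def _dual_exp(t: np.ndarray, tau_rise: float, tau_decay: float) -> np.ndarray:
    """Difference-of-exponentials burst kernel, zero for t < 0, peak 1."""
    out = np.zeros_like(t, dtype=float)
    pos = t >= 0
    tp = t[pos]
    k = np.exp(-tp / tau_decay) - np.exp(-tp / tau_rise)
    t_peak = tau_decay * tau_rise / (tau_decay - tau_rise) * np.log(tau_decay / tau_rise)
    peak = np.exp(-t_peak / tau_decay) - np.exp(-t_peak / tau_rise)
    out[pos] = k / peak
    return out


def _raised_cosine(t: np.ndarray, start: float, length: float) -> np.ndarray:
    """Hann bump over [start, start+length), peak 1 at the midpoint."""
    out = np.zeros_like(t, dtype=float)
    m = (t >= start) & (t < start + length)
    out[m] = np.sin(np.pi * (t[m] - start) / length) ** 2
    return out


def _profile_shape(
    condition: StimulusCondition,
    t: np.ndarray,
    config: GeneratorConfig,
    second_burst: bool,
) -> np.ndarray:
    sched = config.schedule
    on = sched.stimulus_on_s
    stim = condition.stimulus_type
    if stim is StimulusType.DOWEL:
        tr, td = config.dowel_tau
        shape = _dual_exp(t, tr, td) + config.offset_burst_scale * _dual_exp(t - on, tr, td)
        shape = shape + config.tactile_sustained_level * ((t >= 0) & (t < on))
    elif stim is StimulusType.BRUSH:
        tr, td = config.brush_tau
        shape = _dual_exp(t, tr, td) + config.offset_burst_scale * _dual_exp(t - on, tr, td)
        if second_burst:
            shape = shape + 0.6 * _dual_exp(t - 0.060, tr, td)
        shape = shape + config.tactile_sustained_level * ((t >= 0) & (t < on))
    else:
        shape = _raised_cosine(t, 0.0, on)
        shape = shape + config.return_burst_scale * _raised_cosine(t, on, sched.return_s)
    return shape


@lru_cache(maxsize=128)
def _shape_norm(key: tuple) -> float:
    """Integral of the raw profile shape over [0, 1] s (quadrature)."""
    condition_label, cfg_key, second_burst = key
    condition = StimulusCondition.from_label(condition_label)
    config = _CONFIG_CACHE[cfg_key]
    tq = np.arange(0.0, 1.0, 1e-4)
    shape = _profile_shape(condition, tq, config, second_burst)
    return float(np.trapezoid(shape, tq))


# Cache of configs participating in the lru-cached normalization above.
_CONFIG_CACHE: dict = {}


def _config_key(config: GeneratorConfig) -> tuple:
    key = (
        config.schedule.stimulus_on_s,
        config.schedule.return_s,
        config.dowel_tau,
        config.brush_tau,
        config.offset_burst_scale,
        config.return_burst_scale,
        config.tactile_sustained_level,
    )
    _CONFIG_CACHE[key] = config
    return key


def response_rate_profile(
    condition: StimulusCondition,
    t,
    config: GeneratorConfig | None = None,
    second_burst: bool = False,
) -> np.ndarray:
    """Instantaneous firing rate (events/s) on a unit-gain electrode.

    ``t`` is time in seconds since stimulus onset (scalar or array; may be
    negative).  The profile is normalized so that its integral over the
    first second equals ``target_spike_count`` for the condition; outside
    the stimulus phases the rate is the ``residual_rate_hz`` baseline
    (zero by default).
    """
    if config is None:
        config = GeneratorConfig()
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    shape = _profile_shape(condition, t_arr, config, second_burst)
    target = float(config.target_spike_count[condition.stimulus_type])
    norm = _shape_norm((condition.label, _config_key(config), second_burst))
    rate = np.zeros_like(shape) if target == 0 or norm == 0 else target * shape / norm
    rate = rate + config.residual_rate_hz
    return rate if np.ndim(t) else float(rate[0])


# ---------------------------------------------------------------------------
# Spike template and amplitude calibration
# ---------------------------------------------------------------------------


def spike_template(
    fs: float,
    width_ms: float = 1.0,
    asymmetry: float = 0.45,
    carrier_hz: float = 1400.0,
) -> np.ndarray:
    """Biphasic, negative-leading extracellular spike template (~1 ms).

    A Gaussian-windowed sine (Gabor wavelet) centered mid-band of the
    550–3300 Hz spiking band, with the negative lobes scaled by
    ``asymmetry`` and the largest positive lobe normalized to 1.  Its
    energy is concentrated in-band, so the HF band-pass preserves the
    shape without ringing side-peaks that a square-edged biphasic pulse
    would produce.  Raises if the template would span fewer than 3
    samples at ``fs``.
    """
    n = int(round(width_ms / 1000.0 * fs))
    if n < 3:
        raise ValueError(
            f"fs={fs} Hz cannot represent a {width_ms} ms spike template "
            f"({n} samples < 3)"
        )
    t = (np.arange(n) - (n - 1) / 2.0) / fs
    sigma = width_ms / 1000.0 / 7.0
    w = np.sin(2.0 * np.pi * carrier_hz * t) * np.exp(-0.5 * (t / sigma) ** 2)
    w[w < 0] *= asymmetry
    peak = w.max()
    if peak <= 0:  # pragma: no cover - the wavelet always has a positive lobe
        raise ValueError("degenerate spike template")
    return w / peak


@lru_cache(maxsize=16)
def _template_calibration(
    fs: float, width_ms: float, asymmetry: float, carrier_hz: float
) -> tuple:
    """(template, scale) so an injected spike of amplitude A has
    post-HF-filter prominence ~= A.

    The calibration passes a unit template through the standard HF
    band-pass and measures its peak prominence; if the sampling rate is
    too low for that filter the raw template prominence is used.
    """
    tpl = spike_template(fs, width_ms, asymmetry, carrier_hz)
    n_pad = max(int(0.05 * fs), 4 * len(tpl))
    x = np.zeros(2 * n_pad + len(tpl))
    x[n_pad : n_pad + len(tpl)] = tpl
    try:
        y = sigproc.hf_bandpass(sigproc.TimeSeries(x, fs)).samples
    except ValueError:
        y = x
    # Same 2 ms prominence locality the spike detector uses by default.
    wlen = max(3, int(round(2.0 / 1000.0 * fs)) | 1)
    peaks, props = sps.find_peaks(y, prominence=0.05, wlen=wlen)
    if len(peaks) == 0:  # pragma: no cover - filter never annihilates the template
        raise RuntimeError("spike template vanished under the HF band-pass")
    prom = float(props["prominences"].max())
    return tpl, 1.0 / prom


# ---------------------------------------------------------------------------
# Trial and cohort generation
# ---------------------------------------------------------------------------

_BIN_S = 5e-4  # Poisson discretization bin (0.5 ms)


def _trial_span(condition: StimulusCondition, config: GeneratorConfig) -> tuple[float, float]:
    """(pre_onset_s, post_onset_s) of the synthesized trace."""
    base_post = config.schedule.duration_s(condition)
    post = base_post
    if config.min_post_onset_s is not None:
        post = max(post, config.min_post_onset_s)
    return config.pre_onset_s, post


def _animal_effects(config: GeneratorConfig, animal_id: int, seed: int) -> dict:
    """Per-animal multiplicative random effects (log-normal, mean ~1)."""
    rng = np.random.default_rng(np.random.SeedSequence((seed, animal_id, 0xA11)))
    sd = config.animal_effect_sd
    return {
        "rate": float(rng.lognormal(-0.5 * sd**2, sd)),
        "amp": float(rng.lognormal(-0.5 * sd**2, sd)),
        "gain": rng.lognormal(-0.5 * sd**2, sd, size=config.n_electrodes),
    }


def generate_trial(
    condition: StimulusCondition,
    config: GeneratorConfig,
    rng: np.random.Generator,
    animal_id: int = 0,
    trial_id: int = 0,
    animal_effects: dict | None = None,
) -> Trial:
    """Synthesize one labeled multi-electrode trial.

    Spike times are drawn from a binned Bernoulli realization of the
    inhomogeneous rate under ``response_rate_profile`` (at most one event
    per 0.5 ms bin, jittered within the bin center), which keeps the
    expected event count exact while guaranteeing neighbouring events stay
    resolvable as distinct peaks; each spike contributes an
    amplitude-jittered biphasic template mixed across electrodes by the
    limb's gain row, on top of additive noise.
    """
    fs = config.fs
    tpl, tpl_scale = _template_calibration(
        fs, config.spike_width_ms, config.spike_asymmetry, config.spike_carrier_hz
    )
    pre_s, post_s = _trial_span(condition, config)
    n = int(round((pre_s + post_s) * fs))
    onset = int(round(pre_s * fs))
    eff = animal_effects or {"rate": 1.0, "amp": 1.0, "gain": np.ones(config.n_electrodes)}

    second_burst = False
    if condition.stimulus_type is StimulusType.BRUSH and config.brush_double_burst_p > 0:
        second_burst = bool(rng.random() < config.brush_double_burst_p)

    # One Bernoulli draw per 0.5 ms bin with p = rate * dt (expected count
    # preserved exactly for p < the 0.95 cap); events sit near bin centers
    # so any two are >= 0.3 ms apart and never merge into one peak.
    edges = np.arange(-pre_s, post_s, _BIN_S)
    rate = response_rate_profile(condition, edges + _BIN_S / 2.0, config, second_burst)
    p = np.minimum(np.maximum(rate, 0.0) * _BIN_S * eff["rate"], 0.95)
    occupied = np.flatnonzero(rng.random(len(edges)) < p)
    # +-0.05 ms jitter: enough to break the bin lattice, small enough that
    # events in adjacent bins stay >= 0.4 ms apart (always two distinct peaks).
    jitter = (rng.random(len(occupied)) - 0.5) * 0.2
    spike_t = edges[occupied] + (0.5 + jitter) * _BIN_S
    spike_idx = onset + np.round(spike_t * fs).astype(int)

    base_amp = float(config.base_spike_amp_uV[condition.stimulus_type]) * eff["amp"]
    cv = config.amp_jitter_cv
    if cv > 0:
        sigma = np.sqrt(np.log(1.0 + cv**2))
        jitter = rng.lognormal(-0.5 * sigma**2, sigma, size=len(spike_idx))
    else:
        jitter = np.ones(len(spike_idx))
    amps = base_amp * jitter * tpl_scale

    mono = np.zeros(n)
    half = len(tpl) // 2
    for idx, a in zip(spike_idx, amps):
        lo = idx - half
        hi = lo + len(tpl)
        s0, s1 = max(lo, 0), min(hi, n)
        if s0 >= s1:
            continue
        mono[s0:s1] += a * tpl[s0 - lo : s1 - lo]

    gains = np.asarray(config.electrode_gain[condition.limb], dtype=float) * eff["gain"]
    sig = gains[:, None] * mono[None, :]

    if config.noise_sd_uV > 0:
        sig = sig + rng.normal(0.0, config.noise_sd_uV, size=sig.shape)
    if config.lf_noise_sd_uV > 0:
        # Slow (<40 Hz) noise floor, shared shaping filter across electrodes.
        white = rng.normal(0.0, 1.0, size=sig.shape)
        sos = sps.butter(2, 40.0, btype="lowpass", fs=fs, output="sos")
        slow = sps.sosfilt(sos, white, axis=1)
        std = slow.std()
        if std > 0:
            sig = sig + config.lf_noise_sd_uV * slow / std

    return Trial(sig, condition, onset, fs, animal_id, trial_id)


def _trial_rng(seed: int, animal_id: int, trial_counter: int) -> np.random.Generator:
    # Counter-based substreams: any subset of trials is reproducible
    # without generating the rest of the cohort.
    return np.random.default_rng(np.random.SeedSequence((seed, animal_id, trial_counter)))


def iter_animal_trials(
    config: GeneratorConfig,
    animal_id: int,
    seed: int,
    conditions: Sequence[StimulusCondition] = ALL_CONDITIONS,
) -> Iterator[Trial]:
    """Lazily generate one animal's trials (memory-light at full scale)."""
    eff = _animal_effects(config, animal_id, seed)
    for counter, (cond, _s, _t) in enumerate(config.schedule.enumerate_trials(conditions)):
        rng = _trial_rng(seed, animal_id, counter)
        yield generate_trial(cond, config, rng, animal_id, counter, eff)


def generate_animal(
    config: GeneratorConfig,
    animal_id: int,
    seed: int,
    conditions: Sequence[StimulusCondition] = ALL_CONDITIONS,
) -> AnimalDataset:
    """Materialize one synthetic animal (all conditions, full schedule)."""
    n_trials = len(config.schedule.enumerate_trials(conditions))
    est_gb = n_trials * config.n_electrodes * 7.2 * config.fs * 8 / 1e9
    if est_gb > 4.0:
        warnings.warn(
            f"materializing ~{est_gb:.1f} GB of traces; consider iter_animal_trials "
            f"or a desk-scale config",
            ResourceWarning,
            stacklevel=2,
        )
    trials = list(iter_animal_trials(config, animal_id, seed, conditions))
    return AnimalDataset(animal_id, trials, config, seed)


def generate_cohort(
    config: GeneratorConfig, n_animals: int, seed: int
) -> list[AnimalDataset]:
    """Generate ``n_animals`` independent animals under one master seed."""
    return [generate_animal(config, a, seed) for a in range(n_animals)]
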