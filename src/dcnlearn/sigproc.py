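"""Deterministic signal conditioning for DCN surface potentials.

Three filtering stages are used throughout the pipeline, all zero-phase
(forward-backward) Butterworth filters:

* ``hf_bandpass`` — 550–3300 Hz, order 5: isolates multiunit spiking.
* ``lf_envelope`` — full-wave rectification of the HF trace followed by an
  80 Hz order-5 low-pass: the burst envelope.
* ``broadband`` — 4–5000 Hz, order 8: conditioning before spectral features.

Spectral features are "peak power spectral density" within fixed bands,
estimated from a Hann-tapered, zero-padded periodogram of the analysis
window (zero-padding keeps the frequency grid at <= 1 Hz even for short
windows, so the low LF bands always contain bins).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
from scipy import signal as sps

__all__ = [
    "TimeSeries",
    "FilterSpec",
    "FeatureWindow",
    "HF_BANDPASS",
    "LF_LOWPASS",
    "BROADBAND",
    "hf_bandpass",
    "lf_envelope",
    "broadband",
    "band_peak_psd",
    "window_slice",
]


@dataclass(frozen=True)
class TimeSeries:
    """A single-channel voltage trace in microvolts sampled at ``fs`` Hz."""

    samples: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        if self.fs <= 0:
            raise ValueError(f"fs must be positive, got {self.fs}")

    @property
    def n(self) -> int:
        return len(self.samples)

    @property
    def duration_s(self) -> float:
        return self.n / self.fs


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth filter definition; ``zero_phase`` is always true here."""

    kind: str
    corners: tuple  # Hz; (low, high) for bandpass, (cut,) for lowpass
    order: int
    zero_phase: bool = True


HF_BANDPASS = FilterSpec("hf_bandpass", (550.0, 3300.0), 5)
LF_LOWPASS = FilterSpec("lf_lowpass", (80.0,), 5)
BROADBAND = FilterSpec("broadband", (4.0, 5000.0), 8)


@dataclass(frozen=True)
class FeatureWindow:
    """Analysis window relative to stimulus onset (start may be negative)."""

    start_ms: float
    length_ms: float

    def __post_init__(self) -> None:
        if self.length_ms <= 0:
            raise ValueError(f"window length must be > 0 ms, got {self.length_ms}")

    @property
    def end_ms(self) -> float:
        return self.start_ms + self.length_ms

    @property
    def center_ms(self) -> float:
        return self.start_ms + self.length_ms / 2.0

    def to_slice(self, fs: float, onset_sample: int, n: int) -> slice:
        start = onset_sample + int(round(self.start_ms / 1000.0 * fs))
        stop = start + int(round(self.length_ms / 1000.0 * fs))
        if start < 0 or stop > n:
            raise ValueError(
                f"window [{self.start_ms}, {self.end_ms}] ms maps to samples "
                f"[{start}, {stop}) outside the trial span [0, {n})"
            )
        if stop <= start:
            raise ValueError("window is empty at this sampling rate")
        return slice(start, stop)


@lru_cache(maxsize=64)
def _design_sos(kind: str, fs: float) -> np.ndarray:
    """Second-order-sections design, cached per (filter kind, fs)."""
    nyq = fs / 2.0
    if kind == "hf_bandpass":
        spec = HF_BANDPASS
        if nyq <= spec.corners[1]:
            raise ValueError(
                f"fs={fs} Hz too low for the {spec.corners[0]}-{spec.corners[1]} Hz "
                f"band-pass: Nyquist ({nyq} Hz) must exceed {spec.corners[1]} Hz"
            )
        return sps.butter(spec.order, spec.corners, btype="bandpass", fs=fs, output="sos")
    if kind == "lf_lowpass":
        spec = LF_LOWPASS
        if nyq <= spec.corners[0]:
            raise ValueError(f"fs={fs} Hz too low for an {spec.corners[0]} Hz low-pass")
        return sps.butter(spec.order, spec.corners[0], btype="lowpass", fs=fs, output="sos")
    if kind == "broadband":
        spec = BROADBAND
        low, high = spec.corners
        if nyq <= low:
            raise ValueError(f"fs={fs} Hz too low for the broadband filter")
        if nyq <= high:
            # Upper corner at/above Nyquist: the band ceiling is Nyquist itself,
            # so only the high-pass edge remains meaningful.
            return sps.butter(spec.order, low, btype="highpass", fs=fs, output="sos")
        return sps.butter(spec.order, (low, high), btype="bandpass", fs=fs, output="sos")
    raise ValueError(f"unknown filter kind {kind!r}")


def _zero_phase(kind: str, x: TimeSeries) -> TimeSeries:
    sos = _design_sos(kind, float(x.fs))
    y = sps.sosfiltfilt(sos, np.asarray(x.samples, dtype=float), padtype="odd")
    return TimeSeries(y, x.fs)


def hf_bandpass(x: TimeSeries) -> TimeSeries:
    """Zero-phase 550–3300 Hz order-5 Butterworth band-pass (spiking band)."""
    return _zero_phase("hf_bandpass", x)


def lf_envelope(x_hf: TimeSeries) -> TimeSeries:
    """Full-wave rectification then zero-phase 80 Hz order-5 low-pass.

    The input should already be HF band-passed; the output is the
    low-frequency burst envelope (nonnegative up to filter ringing).
    """
    rect = TimeSeries(np.abs(np.asarray(x_hf.samples, dtype=float)), x_hf.fs)
    return _zero_phase("lf_lowpass", rect)


def broadband(x: TimeSeries) -> TimeSeries:
    """Zero-phase 4–5000 Hz order-8 Butterworth conditioning filter.

    When the Nyquist frequency is at or below 5000 Hz the upper corner is
    implied by Nyquist and only the 4 Hz high-pass edge is applied.
    """
    return _zero_phase("broadband", x)


def window_slice(x: TimeSeries, window: FeatureWindow, onset_sample: int = 0) -> np.ndarray:
    """Samples of ``x`` within ``window`` (relative to ``onset_sample``)."""
    return np.asarray(x.samples)[window.to_slice(x.fs, onset_sample, x.n)]


def _periodogram(seg: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    # NFFT chosen so the frequency grid is <= 1 Hz: short analysis windows
    # (e.g. 60 ms) cannot natively resolve the 4-8 Hz band, so the
    # zero-padded periodogram provides a deterministic interpolation.
    n = len(seg)
    nfft = 1 << int(np.ceil(np.log2(max(n, fs))))
    f, pxx = sps.periodogram(
        seg, fs=fs, window="hann", nfft=nfft, detrend=False, scaling="density"
    )
    return f, pxx


def band_peak_psd(
    x: TimeSeries,
    window: FeatureWindow,
    band: tuple[float, float],
    onset_sample: int = 0,
) -> float:
    """Peak spectral density (μV²/Hz) of the windowed segment inside ``band``.

    The estimate is the maximum of a Hann-tapered zero-padded periodogram
    over the frequency bins intersecting ``band``.
    """
    lo, hi = band
    if not (0.0 < lo < hi):
        raise ValueError(f"invalid band {band}")
    if hi >= x.fs / 2.0 and lo >= x.fs / 2.0:
        raise ValueError(f"band {band} lies entirely above Nyquist ({x.fs / 2.0} Hz)")
    seg = window_slice(x, window, onset_sample)
    f, pxx = _periodogram(seg, float(x.fs))
    mask = (f >= lo) & (f <= hi)
    if not mask.any():  # pragma: no cover - grid is always <= 1 Hz
        mask = np.argmin(np.abs(f - (lo + hi) / 2.0))
        return float(pxx[mask])
    return float(pxx[mask].max())
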