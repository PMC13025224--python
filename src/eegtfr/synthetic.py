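"""Synthetic EEG cohorts and analytic test signals with known ground truth.

The generator emulates resting-state EEG well enough to exercise every
downstream stage of the pipeline without any clinical data: a 1/f
background, band-limited oscillations in the five classical rhythms
(delta through low gamma), optional line interference and white sensor
noise.  The class difference between responders and non-responders is a
multiplicative band-power scaling applied only at a configurable set of
channels, so its location and size are exactly known and recoverable by
band-power analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .records import MONTAGE_10_20, EEGRecording

#: Classical EEG rhythm bands in Hz.
BANDS: dict[str, tuple[float, float]] = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 13.0),
    "beta": (13.0, 30.0),
    "gamma": (30.0, 60.0),
}

#: Baseline per-band RMS amplitude in µV, loosely matching eyes-closed
#: resting EEG (posterior-dominant alpha, weak gamma).
_BASE_BAND_RMS = {
    "delta": 5.0,
    "theta": 3.5,
    "alpha": 7.0,
    "beta": 2.0,
    "gamma": 1.0,
}

_BACKGROUND_RMS_UV = 8.0  # 1/f background level


def _default_band_powers() -> dict:
    # Relative band *power* (variance) per class at the effect channels;
    # a 3:1 alpha ratio is a strong but physiologically plausible
    # eyes-closed posterior-alpha difference.
    return {"alpha": {"R": 3.0, "NR": 1.0}}


@dataclass
class SyntheticCohortSpec:
    """Conditions for one simulated responder/non-responder cohort.

    ``band_powers`` maps band name -> {class -> relative power multiplier}
    applied at ``effect_channels`` only; every other channel (and every
    band not listed) uses multiplier 1 for both classes, so channels off
    the effect set carry no class information by construction.
    """

    n_responders: int = 10
    n_nonresponders: int = 10
    n_channels: int = 19
    duration_s: float = 300.0
    fs: float = 256.0
    band_powers: dict = field(default_factory=_default_band_powers)
    effect_channels: list = field(default_factory=lambda: ["O1", "O2"])
    line_freq: float = 50.0
    line_amp_uv: float = 1.0
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_channels < 1:
            raise ValueError("n_channels must be >= 1")
        if not (self.duration_s > 0 and self.fs > 0):
            raise ValueError("duration_s and fs must be positive")
        if self.n_responders < 0 or self.n_nonresponders < 0:
            raise ValueError("cohort sizes must be non-negative")
        for band in self.band_powers:
            if band not in BANDS:
                raise ValueError(f"unknown band {band!r}; known: {sorted(BANDS)}")

    @property
    def channel_labels(self) -> list:
        if self.n_channels <= len(MONTAGE_10_20):
            return list(MONTAGE_10_20[: self.n_channels])
        extra = [f"EX{i}" for i in range(self.n_channels - len(MONTAGE_10_20))]
        return list(MONTAGE_10_20) + extra


@dataclass
class ToneSpec:
    """A deterministic multi-tone test signal (oracle input)."""

    frequencies: list
    amplitudes: list | None = None
    duration_s: float = 15.0
    fs: float = 512.0
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if self.amplitudes is None:
            self.amplitudes = [1.0] * len(self.frequencies)
        if len(self.amplitudes) != len(self.frequencies):
            raise ValueError("need one amplitude per frequency")
        for f in self.frequencies:
            if not f < self.fs / 2:
                raise ValueError(
                    f"tone at {f} Hz is not below the Nyquist frequency "
                    f"{self.fs / 2} Hz"
                )


def pink_noise(n: int, rng: np.random.Generator, beta: float = 1.0) -> np.ndarray:
    """Unit-variance 1/f^beta noise via spectral shaping of white noise."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]  # avoid division by zero at DC
    spec /= f ** (beta / 2.0)
    x = np.fft.irfft(spec, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _band_component(n: int, fs: float, band: tuple, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance band-limited Gaussian oscillation."""
    lo, hi = band
    hi = min(hi, 0.999 * fs / 2)
    if lo >= hi:
        return np.zeros(n)
    sos = sps.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    x = sps.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def generate_recording(spec: SyntheticCohortSpec, label: str, subject_id: str,
                       rng: np.random.Generator) -> EEGRecording:
    """One synthetic recording of the given class."""
    n = int(round(spec.duration_s * spec.fs))
    labels = spec.channel_labels
    effect = set(spec.effect_channels)
    data = np.empty((spec.n_channels, n))
    for ci, ch in enumerate(labels):
        x = _BACKGROUND_RMS_UV * pink_noise(n, rng)
        for band, (lo, hi) in BANDS.items():
            rms = _BASE_BAND_RMS[band]
            mult = 1.0
            if ch in effect and band in spec.band_powers:
                mult = float(spec.band_powers[band][label])
            x += rms * np.sqrt(mult) * _band_component(n, spec.fs, (lo, hi), rng)
        if spec.line_amp_uv and spec.line_freq < spec.fs / 2:
            phase = rng.uniform(0, 2 * np.pi)
            t = np.arange(n) / spec.fs
            x += spec.line_amp_uv * np.sin(2 * np.pi * spec.line_freq * t + phase)
        if spec.noise_sd:
            x += spec.noise_sd * rng.standard_normal(n)
        data[ci] = x
    return EEGRecording(samples=data, fs=spec.fs, channel_labels=labels,
                        subject_id=subject_id, label=label)


def generate_cohort(spec: SyntheticCohortSpec) -> list:
    """Generate ``n_responders + n_nonresponders`` labelled recordings.

    Deterministic: the same spec (including seed) yields bit-identical
    sample arrays.  Responders come first.
    """
    rng = np.random.default_rng(spec.seed)
    recs = []
    for i in range(spec.n_responders):
        recs.append(generate_recording(spec, "R", f"R{i:02d}", rng))
    for i in range(spec.n_nonresponders):
        recs.append(generate_recording(spec, "NR", f"NR{i:02d}", rng))
    return recs


def generate_tones(spec: ToneSpec) -> np.ndarray:
    """Sum of sinusoids plus optional white noise; single channel."""
    n = int(round(spec.duration_s * spec.fs))
    t = np.arange(n) / spec.fs
    x = np.zeros(n)
    for f, a in zip(spec.frequencies, spec.amplitudes):
        x += a * np.cos(2 * np.pi * f * t)
    if spec.noise_sd:
        rng = np.random.default_rng(spec.seed)
        x += spec.noise_sd * rng.standard_normal(n)
    return x


def band_power(x: np.ndarray, fs: float, band: tuple, nperseg: int | None = None) -> float:
    """Average Welch power spectral density of ``x`` inside ``band`` (Hz)."""
    if nperseg is None:
        nperseg = min(len(x), int(4 * fs))
    f, pxx = sps.welch(x, fs=fs, nperseg=nperseg)
    lo, hi = band
    mask = (f >= lo) & (f <= hi)
    if not mask.any():
        warnings.warn("band contains no Welch frequency bins")
        return 0.0
    return float(np.trapezoid(pxx[mask], f[mask]))
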