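"""Time-frequency image representations: CWT scalograms, aggregate VMD
spectrograms, their pixel-wise fusion, and PNG rendering.

All three representations are magnitude images over a time x frequency
grid; raw magnitude (not dB) maps to pixel intensity.  Fusion averages
the two min-max-normalised source images pixel by pixel after they have
been resampled to a common grid.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image

from .vmd import VMDConfig, vmd_decompose

REPRS = ("CWT", "VMD", "FUSION")


@dataclass
class CWTConfig:
    """Analytic-Morlet scalogram parameters.

    The frequency grid is logarithmic with ``voices_per_octave`` rows
    per octave spanning [fmin, fmax]; ``omega0`` is the Morlet centre
    frequency in rad/sample-of-scale (6 gives the standard ~1 octave
    resolution trade-off).
    """

    omega0: float = 6.0
    voices_per_octave: int = 12
    fmin: float = 2.0
    fmax: float = 60.0

    def __post_init__(self):
        if not (0 < self.fmin < self.fmax):
            raise ValueError("need 0 < fmin < fmax")
        if self.voices_per_octave < 1:
            raise ValueError("voices_per_octave must be >= 1")


@dataclass
class STFTConfig:
    """Hamming-window STFT parameters for the VMD spectrogram.

    Defaults give hop = win_len - overlap = 6 samples and a 7680-point
    FFT at 512 Hz (1/15 Hz bin spacing over 15-s epochs).
    """

    win_len: int = 256
    overlap: int = 250
    nfft: int = 7680
    fs: float = 512.0
    fmax_display: float = 60.0

    def __post_init__(self):
        if not self.overlap < self.win_len:
            raise ValueError("overlap must be smaller than win_len")
        if self.nfft < self.win_len:
            raise ValueError("nfft must be >= win_len")

    @property
    def hop(self) -> int:
        return self.win_len - self.overlap


@dataclass
class TFImage:
    """A 2-D time-frequency magnitude array with axes and identity metadata."""

    values: np.ndarray            # (n_freqs, n_times), nonnegative
    time_axis: np.ndarray         # seconds
    freq_axis: np.ndarray         # Hz, monotone increasing
    repr: str                     # "CWT" | "VMD" | "FUSION"
    channel_label: str = ""
    subject_id: str = ""
    epoch_index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.freq_axis = np.asarray(self.freq_axis, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        if self.repr not in REPRS:
            raise ValueError(f"repr must be one of {REPRS}")
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (freq x time)")
        if len(self.freq_axis) != self.values.shape[0]:
            raise ValueError("freq_axis length must match the number of rows")
        if np.any(np.diff(self.freq_axis) <= 0):
            raise ValueError("freq_axis must be strictly increasing")

    def copy_with(self, **changes) -> "TFImage":
        return replace(self, **changes)


def cwt_scalogram(epoch_channel: np.ndarray, fs: float,
                  cfg: CWTConfig | None = None, *,
                  channel_label: str = "", subject_id: str = "",
                  epoch_index: int = 0) -> TFImage:
    """Analytic-Morlet CWT magnitude image of one channel.

    The transform is computed in the FFT domain with the one-sided
    Morlet kernel ``2 exp(-(s w - omega0)^2 / 2)`` for ``w > 0`` (zero
    for ``w <= 0``), so negative frequencies are fully suppressed and
    an equal-amplitude tone produces equal magnitude on every row
    (L1-style normalisation).  Rows are log-spaced at
    ``voices_per_octave`` per octave covering [fmin, fmax].
    """
    cfg = cfg or CWTConfig()
    x = np.asarray(epoch_channel, dtype=float).ravel()
    if not np.all(np.isfinite(x)):
        raise ValueError("input contains non-finite values")
    nyq = fs / 2
    fmax = cfg.fmax
    if fmax > nyq:
        warnings.warn(f"fmax {fmax} Hz clipped to Nyquist {nyq} Hz")
        fmax = nyq

    n_voices = cfg.voices_per_octave
    n_rows = int(np.floor(n_voices * np.log2(fmax / cfg.fmin))) + 1
    freqs = fmax * 2.0 ** (-np.arange(n_rows) / n_voices)   # descending
    freqs = freqs[::-1]                                      # ascending
    scales = cfg.omega0 * fs / (2 * np.pi * freqs)           # samples

    # reflect-pad to suppress wrap-around at the largest scale
    from scipy import fft as sfft

    pad = int(min(len(x), np.ceil(4 * scales.max())))
    xp = np.pad(x, pad, mode="reflect") if pad > 0 else x
    n = sfft.next_fast_len(len(xp))
    xf = sfft.fft(xp, n=n)
    w = 2 * np.pi * sfft.fftfreq(n)                          # rad/sample
    pos = w > 0

    psi_hat = np.zeros((n_rows, n))
    psi_hat[:, pos] = 2.0 * np.exp(
        -0.5 * (scales[:, None] * w[None, pos] - cfg.omega0) ** 2)
    wcoef = sfft.ifft(xf[None, :] * psi_hat, axis=1)
    mags = np.abs(wcoef[:, pad:pad + len(x)])

    t = np.arange(len(x)) / fs
    return TFImage(values=mags, time_axis=t, freq_axis=freqs, repr="CWT",
                   channel_label=channel_label, subject_id=subject_id,
                   epoch_index=epoch_index)


def stft_spectrogram(mode: np.ndarray, cfg: STFTConfig | None = None):
    """Complex Hamming-window STFT of one waveform.

    Returns ``(S, freqs, times)`` where ``S`` has shape
    ``(n_freqs, n_frames)`` over the one-sided FFT grid; frames are the
    fully-contained window positions at hop ``win_len - overlap``.
    """
    cfg = cfg or STFTConfig()
    x = np.asarray(mode, dtype=float).ravel()
    if len(x) < cfg.win_len:
        raise ValueError(
            f"input of {len(x)} samples shorter than the {cfg.win_len}-sample window"
        )
    win = np.hamming(cfg.win_len)
    frames = np.lib.stride_tricks.sliding_window_view(x, cfg.win_len)[::cfg.hop]
    spec = np.fft.rfft(frames * win, n=cfg.nfft, axis=1).T   # (n_freqs, n_frames)
    freqs = np.fft.rfftfreq(cfg.nfft, d=1.0 / cfg.fs)
    times = (np.arange(frames.shape[0]) * cfg.hop + (cfg.win_len - 1) / 2) / cfg.fs
    return spec, freqs, times


def aggregate_vmd_spectrogram(modes: np.ndarray, cfg: STFTConfig | None = None, *,
                              channel_label: str = "", subject_id: str = "",
                              epoch_index: int = 0) -> TFImage:
    """Magnitude of the complex sum of per-mode STFT spectrograms.

    The complex spectrograms of all modes are accumulated and the
    magnitude of the sum is restricted to [0, fmax_display] Hz.  By
    linearity of the STFT this equals the spectrogram of the summed
    modes; summing complex values (not magnitudes) preserves phase
    relationships between the narrowband modes.
    """
    cfg = cfg or STFTConfig()
    if isinstance(modes, np.ndarray) and modes.dtype != object:
        mode_list = list(np.atleast_2d(modes))
    else:
        mode_list = [np.asarray(m, dtype=float).ravel() for m in modes]
    if len({len(m) for m in mode_list}) != 1:
        raise ValueError("all modes must have the same length")
    modes = np.stack(mode_list)
    total = None
    freqs = times = None
    for u in modes:
        s, freqs, times = stft_spectrogram(u, cfg)
        total = s if total is None else total + s
    mag = np.abs(total)
    keep = freqs <= cfg.fmax_display
    # drop the zero row so the frequency axis stays strictly increasing
    # down to DC; keep bin 0 (freq 0) is fine for monotonicity
    return TFImage(values=mag[keep], time_axis=times, freq_axis=freqs[keep],
                   repr="VMD", channel_label=channel_label,
                   subject_id=subject_id, epoch_index=epoch_index)


def vmd_image(epoch_channel: np.ndarray, fs: float,
              vmd_cfg: VMDConfig | None = None,
              stft_cfg: STFTConfig | None = None, **meta) -> TFImage:
    """Convenience: VMD decomposition followed by the aggregate spectrogram."""
    res = vmd_decompose(epoch_channel, fs, vmd_cfg)
    cfg = stft_cfg or STFTConfig(fs=fs)
    return aggregate_vmd_spectrogram(res.modes, cfg, **meta)


def minmax_normalise(img: TFImage) -> TFImage:
    """Rescale pixel values to [0, 1]; a constant image maps to all zeros."""
    v = img.values
    if not np.all(np.isfinite(v)):
        raise ValueError("image contains non-finite values")
    lo, hi = v.min(), v.max()
    if hi == lo:
        warnings.warn("constant image: min-max normalisation returns zeros")
        return img.copy_with(values=np.zeros_like(v))
    return img.copy_with(values=(v - lo) / (hi - lo))


def fuse(cwt_img: TFImage, vmd_img: TFImage) -> TFImage:
    """Pixel-wise average of the two min-max-normalised representations.

    Both images must already live on the same H x W grid and refer to
    the same subject, epoch and channel.
    """
    for key in ("subject_id", "epoch_index", "channel_label"):
        a, b = getattr(cwt_img, key), getattr(vmd_img, key)
        if a != b:
            raise ValueError(f"image identity mismatch on {key}: {a!r} vs {b!r}")
    if cwt_img.values.shape != vmd_img.values.shape:
        raise ValueError(
            f"shape mismatch: {cwt_img.values.shape} vs {vmd_img.values.shape}; "
            "resample both images to a common grid first"
        )
    a = minmax_normalise(cwt_img).values
    b = minmax_normalise(vmd_img).values
    return cwt_img.copy_with(values=(a + b) / 2.0, repr="FUSION")


def _resize_bilinear(arr: np.ndarray, out_shape: tuple) -> np.ndarray:
    im = Image.fromarray(arr.astype(np.float32), mode="F")
    resized = im.resize((out_shape[1], out_shape[0]), resample=Image.BILINEAR)
    return np.asarray(resized, dtype=float)


def resample_image(img: TFImage, out_shape: tuple = (224, 224)) -> TFImage:
    """Bilinear resampling of a TF image onto an H x W pixel grid."""
    h, w = out_shape
    vals = _resize_bilinear(img.values, (h, w))
    t = np.linspace(img.time_axis[0], img.time_axis[-1], w)
    f = np.linspace(img.freq_axis[0], img.freq_axis[-1], h)
    return img.copy_with(values=vals, time_axis=t, freq_axis=f)


_JET_LUT: np.ndarray | None = None


def jet_lut() -> np.ndarray:
    """256-entry jet colormap as uint8 RGB (dark blue -> dark red)."""
    global _JET_LUT
    if _JET_LUT is None:
        from matplotlib import colormaps
        lut = colormaps["jet"](np.linspace(0, 1, 256))[:, :3]
        _JET_LUT = np.round(lut * 255).astype(np.uint8)
    return _JET_LUT


def render_rgb(img: TFImage, size: int = 224) -> np.ndarray:
    """Render a TF image to a ``size x size x 3`` uint8 jet-coloured array.

    Per-image min-max to [0, 1] of the raw magnitude, 256-level jet
    lookup, bilinear resize; frequency increases upward (row 0 is the
    highest frequency).
    """
    norm = minmax_normalise(img).values
    idx = np.round(norm * 255).astype(np.intp)
    rgb = jet_lut()[idx].astype(np.float32)                  # H x W x 3
    rgb = rgb[::-1]                                          # high freq on top
    out = np.stack(
        [_resize_bilinear(rgb[..., c], (size, size)) for c in range(3)], axis=-1
    )
    return np.clip(np.round(out), 0, 255).astype(np.uint8)


def image_filename(subject_id: str, epoch_index: int, channel_label: str,
                   repr_tag: str) -> str:
    """``<subject>_<epoch>_<channel>_<repr>.png`` naming convention."""
    for part, name in ((channel_label, "channel_label"), (repr_tag, "repr")):
        if "_" in part:
            raise ValueError(f"{name} must not contain underscores: {part!r}")
    return f"{subject_id}_{epoch_index}_{channel_label}_{repr_tag}.png"


_FILENAME_RE = re.compile(r"^(?P<subject>.+)_(?P<epoch>\d+)_(?P<channel>[^_]+)_(?P<repr>[^_]+)\.png$")


def parse_image_filename(name: str) -> dict:
    """Invert :func:`image_filename`; returns subject/epoch/channel/repr."""
    m = _FILENAME_RE.match(Path(name).name)
    if not m:
        raise ValueError(f"file name {name!r} does not follow the naming convention")
    return {
        "subject_id": m.group("subject"),
        "epoch_index": int(m.group("epoch")),
        "channel_label": m.group("channel"),
        "repr": m.group("repr"),
    }


def render_png(img: TFImage, path, size: int = 224) -> Path:
    """Write the rendered image as a borderless RGB PNG."""
    path = Path(path)
    rgb = render_rgb(img, size=size)
    try:
        Image.fromarray(rgb, mode="RGB").save(path, format="PNG")
    except OSError as exc:
        raise OSError(f"failed to write PNG {path}: {exc}") from exc
    return path
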