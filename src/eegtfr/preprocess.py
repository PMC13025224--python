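"""Preprocessing: zero-phase filtering, common-average re-referencing,
15-s epoching, multiscale-PCA wavelet denoising, and resampling.

The chain applied by :func:`preprocess_recording` is

    band-pass 0.5-70 Hz + 50 Hz notch  ->  CAR  ->  15-s epochs
    ->  optional peak-amplitude rejection  ->  MSPCA  ->  resample to 512 Hz

All filters run forward-reverse (``filtfilt``) so the group delay is
zero.  The amplitude-rejection step is a deliberately simple stand-in
for subspace-reconstruction artifact removal and is off by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from fractions import Fraction

import numpy as np
import pywt
from scipy import signal as sps

from .records import EEGRecording, Epoch

TARGET_FS = 512.0  # common rate shared by both cohorts after preprocessing


@dataclass
class MSPCAConfig:
    """Multiscale PCA denoising parameters.

    wavelet_name : discrete wavelet used for the multilevel decomposition
    level : decomposition depth (9 needs epochs of >= 2**9 samples)
    threshold_rule : only ``"universal"`` (sigma * sqrt(2 ln N), soft)
    pc_rule : only ``"kaiser"`` (retain eigenvalues above their mean)
    """

    wavelet_name: str = "sym4"
    level: int = 9
    threshold_rule: str = "universal"
    pc_rule: str = "kaiser"

    def __post_init__(self):
        if self.level < 1:
            raise ValueError("level must be >= 1")
        if self.threshold_rule != "universal":
            raise ValueError("only the universal threshold rule is supported")
        if self.pc_rule != "kaiser":
            raise ValueError("only Kaiser's eigenvalue criterion is supported")


def bandpass_notch(rec: EEGRecording, low: float = 0.5, high: float = 70.0,
                   notch: float = 50.0, notch_q: float = 35.0) -> EEGRecording:
    """Zero-phase 4th-order Butterworth band-pass plus IIR notch."""
    nyq = rec.fs / 2
    if high >= nyq:
        raise ValueError(f"band-pass edge {high} Hz must be below Nyquist {nyq} Hz")
    sos = sps.butter(4, [low, high], btype="bandpass", fs=rec.fs, output="sos")
    out = sps.sosfiltfilt(sos, rec.samples, axis=1)
    if notch and notch < nyq:
        b, a = sps.iirnotch(notch, Q=notch_q, fs=rec.fs)
        out = sps.filtfilt(b, a, out, axis=1)
    return rec.copy_with(samples=out)


def common_average_reference(rec: EEGRecording) -> EEGRecording:
    """Subtract the instantaneous mean across channels from every channel."""
    if rec.n_channels < 2:
        raise ValueError("common average reference needs at least 2 channels")
    out = rec.samples - rec.samples.mean(axis=0, keepdims=True)
    return rec.copy_with(samples=out)


def segment_epochs(rec: EEGRecording, win_s: float = 15.0,
                   reject_amplitude_uv: float | None = None) -> list:
    """Cut a recording into non-overlapping ``win_s``-second epochs.

    The trailing remainder shorter than one window is discarded.  When
    ``reject_amplitude_uv`` is given, epochs whose peak absolute
    amplitude exceeds it are dropped.
    """
    n_win = int(round(win_s * rec.fs))
    n_epochs = rec.n_times // n_win
    if n_epochs == 0:
        warnings.warn(
            f"recording of {rec.duration_s:.1f}s is shorter than one "
            f"{win_s}s window; no epochs produced"
        )
        return []
    epochs = []
    for i in range(n_epochs):
        seg = rec.samples[:, i * n_win:(i + 1) * n_win]
        if reject_amplitude_uv is not None and np.abs(seg).max() > reject_amplitude_uv:
            continue
        epochs.append(Epoch(samples=seg.copy(), fs=rec.fs, epoch_index=i,
                            subject_id=rec.subject_id, label=rec.label,
                            channel_labels=list(rec.channel_labels),
                            duration_s=win_s))
    return epochs


def _kaiser_pca_filter(coeffs: np.ndarray) -> np.ndarray:
    """PCA across channels; keep components with eigenvalue > mean eigenvalue."""
    mean = coeffs.mean(axis=1, keepdims=True)
    xc = coeffs - mean
    cov = xc @ xc.T / max(xc.shape[1] - 1, 1)
    evals, evecs = np.linalg.eigh(cov)
    keep = evals > evals.mean()
    if not keep.any():  # degenerate (all-equal eigenvalues): keep everything
        return coeffs
    p = evecs[:, keep]
    return p @ (p.T @ xc) + mean


def mspca_denoise(epoch: Epoch, cfg: MSPCAConfig | None = None) -> Epoch:
    """Multiscale PCA denoising of one multichannel epoch.

    The epoch is wavelet-decomposed per channel; at every scale
    (details and final approximation) PCA across channels retains only
    components whose eigenvalue exceeds the mean eigenvalue (Kaiser's
    criterion); detail coefficients are then soft-thresholded with the
    universal threshold sigma*sqrt(2 ln N), sigma estimated per channel
    from the median absolute deviation of the finest-scale details
    (MAD / 0.6745); the signal is reconstructed at the original shape.
    """
    cfg = cfg or MSPCAConfig()
    x = epoch.samples
    n = x.shape[1]
    min_len = 2 ** cfg.level
    if n < min_len:
        raise ValueError(
            f"epoch of {n} samples is too short for a level-{cfg.level} "
            f"decomposition; need at least {min_len} samples"
        )
    coeffs = pywt.wavedec(x, cfg.wavelet_name, level=cfg.level, axis=1)
    # universal soft threshold on the detail coefficients, noise level
    # estimated per channel from the finest-scale details
    sigma = np.median(np.abs(coeffs[-1]), axis=1) / 0.6745
    thr = sigma * np.sqrt(2.0 * np.log(n))
    for lev in range(1, len(coeffs)):
        c = coeffs[lev]
        coeffs[lev] = np.sign(c) * np.maximum(np.abs(c) - thr[:, None], 0.0)
    # Kaiser PCA across channels on the approximation coefficients ...
    coeffs[0] = _kaiser_pca_filter(coeffs[0])
    out = pywt.waverec(coeffs, cfg.wavelet_name, axis=1)[:, :n]
    # ... and on the final reconstruction
    out = _kaiser_pca_filter(out)
    return epoch.copy_with(samples=out)


def resample_epoch(epoch: Epoch, target_fs: float = TARGET_FS) -> Epoch:
    """Polyphase resampling of an epoch to a common sampling rate."""
    if abs(epoch.fs - target_fs) < 1e-9:
        return epoch
    frac = Fraction(int(round(target_fs)), int(round(epoch.fs)))
    out = sps.resample_poly(epoch.samples, frac.numerator, frac.denominator, axis=1)
    return epoch.copy_with(samples=out, fs=target_fs)


def preprocess_recording(rec: EEGRecording, low: float = 0.5, high: float = 70.0,
                         notch: float = 50.0, win_s: float = 15.0,
                         reject_amplitude_uv: float | None = None,
                         denoise: bool = True,
                         mspca: MSPCAConfig | None = None,
                         target_fs: float = TARGET_FS) -> list:
    """Full preprocessing chain for one recording; returns epochs at 512 Hz."""
    rec = bandpass_notch(rec, low=low, high=high, notch=notch)
    rec = common_average_reference(rec)
    epochs = segment_epochs(rec, win_s=win_s, reject_amplitude_uv=reject_amplitude_uv)
    if denoise:
        epochs = [mspca_denoise(ep, mspca) for ep in epochs]
    return [resample_epoch(ep, target_fs) for ep in epochs]
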