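"""Core data containers for multichannel EEG recordings and epochs.

Signals are stored as ``channels x time`` float arrays in microvolts.
Class labels are ``"R"`` (responder) / ``"NR"`` (non-responder).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: The 19-electrode subset of the international 10-20 montage, in the
#: conventional anterior-to-posterior order.
MONTAGE_10_20 = (
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T3", "C3", "Cz", "C4", "T4",
    "T5", "P3", "Pz", "P4", "T6",
    "O1", "O2",
)

LABELS = ("R", "NR")


@dataclass
class EEGRecording:
    """A labelled multichannel EEG recording.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_times)
        Signal in microvolts.
    fs : float
        Sampling frequency in Hz.
    channel_labels : list of str
        One label per row of ``samples``.
    subject_id : str
        Stable subject identifier.
    label : {"R", "NR"} or None
        Therapy-response class, if known.
    therapy : {"SSRI", "rTMS"} or None
        Therapy arm the label refers to.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list = field(default_factory=lambda: list(MONTAGE_10_20))
    subject_id: str = "S0"
    label: str | None = None
    therapy: str | None = None

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        if self.samples.shape[0] != len(self.channel_labels):
            raise ValueError(
                f"{self.samples.shape[0]} signal rows but "
                f"{len(self.channel_labels)} channel labels"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be one of {LABELS}, got {self.label!r}")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_times(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_times / self.fs

    def copy_with(self, **changes) -> "EEGRecording":
        if "samples" not in changes:
            changes["samples"] = self.samples.copy()
        return replace(self, **changes)


@dataclass
class Epoch:
    """A fixed-length segment cut from one recording."""

    samples: np.ndarray
    fs: float
    epoch_index: int
    subject_id: str = "S0"
    label: str | None = None
    channel_labels: list = field(default_factory=lambda: list(MONTAGE_10_20))
    duration_s: float = 15.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channels x time array")
        expected = round(self.duration_s * self.fs)
        if self.samples.shape[1] != expected:
            raise ValueError(
                f"epoch of {self.duration_s}s at {self.fs} Hz must have "
                f"{expected} samples, got {self.samples.shape[1]}"
            )

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    def copy_with(self, **changes) -> "Epoch":
        if "samples" not in changes:
            changes["samples"] = self.samples.copy()
        return replace(self, **changes)
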