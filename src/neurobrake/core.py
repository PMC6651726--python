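"""Core data containers shared across the pipeline.

A driving session pairs an 8-channel EEG stream with a 6-channel IMU
stream (3-axis accelerometer + 3-axis gyroscope) on a common 128 Hz
clock.  Downstream stages operate on 1-s multichannel windows and on
tabular feature datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: International 10-20 electrode labels, fixed channel order everywhere.
EEG_CHANNELS: tuple[str, ...] = ("F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2")

#: Class index convention: 0 = normal driving, 1 = braking intention.
LABEL_NORMAL: int = 0
LABEL_BRAKING: int = 1
LABEL_NAMES: tuple[str, str] = ("normal", "braking")


@dataclass
class SessionRecording:
    """Time-aligned EEG + IMU recording of one driving session.

    Parameters
    ----------
    eeg : ndarray, shape (8, N)
        EEG in microvolts, channel order :data:`EEG_CHANNELS`.
    imu : ndarray, shape (6, N)
        Rows 0-2: accelerometer x/y/z (counts); rows 3-5: gyroscope
        x/y/z (counts).  Shares the EEG sample clock.
    fs : float
        Sampling rate in Hz (both streams).
    truth_events : list of (stimulus_time_s, braking_time_s), optional
        Ground-truth event times for synthetic sessions.
    """

    eeg: np.ndarray
    imu: np.ndarray
    fs: float = 128.0
    channel_names: tuple[str, ...] = EEG_CHANNELS
    truth_events: list[tuple[float, float]] | None = None

    def __post_init__(self) -> None:
        self.eeg = np.asarray(self.eeg, dtype=np.float64)
        self.imu = np.asarray(self.imu, dtype=np.float64)
        if self.eeg.ndim != 2 or self.eeg.shape[0] != 8:
            raise ValueError(
                f"expected 8 EEG channels, got shape {self.eeg.shape}"
            )
        if self.imu.ndim != 2 or self.imu.shape[0] != 6:
            raise ValueError(
                f"expected 6 IMU channels, got shape {self.imu.shape}"
            )
        if self.eeg.shape[1] != self.imu.shape[1]:
            raise ValueError(
                "EEG and IMU must have identical sample counts: "
                f"{self.eeg.shape[1]} != {self.imu.shape[1]}"
            )
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.channel_names) != 8:
            raise ValueError("need exactly 8 channel names")
        if self.truth_events is not None:
            braking = [b for _, b in self.truth_events]
            if any(b2 <= b1 for b1, b2 in zip(braking, braking[1:])):
                raise ValueError("truth_events must be strictly increasing")
            if any(b <= s for s, b in self.truth_events):
                raise ValueError("braking_time must exceed stimulus_time")

    @property
    def n_samples(self) -> int:
        return self.eeg.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    @property
    def accel(self) -> np.ndarray:
        """Accelerometer rows, shape (3, N)."""
        return self.imu[:3]

    @property
    def gyro(self) -> np.ndarray:
        """Gyroscope rows, shape (3, N)."""
        return self.imu[3:]

    @property
    def braking_times(self) -> list[float]:
        """Ground-truth executed-braking times (empty if unknown)."""
        if self.truth_events is None:
            return []
        return [b for _, b in self.truth_events]


@dataclass
class MultichannelWindow:
    """One 1-s analysis window X(t) = [x1..x8]^T of EEG samples."""

    samples: np.ndarray  # (8, L)
    start_time_s: float
    fs: float = 128.0

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=np.float64)
        if self.samples.ndim != 2 or self.samples.shape[0] != 8:
            raise ValueError(
                f"window must be 8 x L, got shape {self.samples.shape}"
            )

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def end_time_s(self) -> float:
        return self.start_time_s + self.n_samples / self.fs


@dataclass
class LabeledSample:
    """A labeled analysis window; features are attached by the featurizer.

    ``label`` uses the fixed convention 0 = normal driving,
    1 = braking intention.  ``source_event_s`` is the executed-braking
    time the window was labeled against (braking class only).
    """

    label: int
    window_end_s: float
    window_index: int
    source_event_s: float | None = None
    features: np.ndarray | None = None


@dataclass
class DatasetTable:
    """Feature matrix + labels + provenance metadata.

    ``meta`` records at least ``feature`` ("bandpower" | "ar"),
    ``ar_order`` (AR only), ``step_ms`` and ``pre_braking_ms`` so the
    expected feature dimension can be validated: 40 for band power,
    8 x (order + 1) for AR (coefficients + innovation variance).
    """

    features: np.ndarray  # (M, D)
    labels: np.ndarray  # (M,), values in {0, 1}
    meta: dict = field(default_factory=dict)
    window_end_s: np.ndarray | None = None
    groups: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.features = np.asarray(self.features, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        if self.features.ndim != 2:
            raise ValueError("features must be 2-D (samples x dims)")
        if self.labels.shape != (self.features.shape[0],):
            raise ValueError("labels length must match feature rows")
        if self.groups is not None:
            self.groups = np.asarray(self.groups)
            if self.groups.shape != self.labels.shape:
                raise ValueError("groups length must match feature rows")
        kind = self.meta.get("feature")
        d = self.features.shape[1]
        if kind == "bandpower" and d != 40:
            raise ValueError(f"bandpower features must have D=40, got {d}")
        if kind == "ar":
            order = self.meta.get("ar_order")
            if order is not None and d != 8 * (int(order) + 1):
                raise ValueError(
                    "AR features must have D=8*(order+1)="
                    f"{8 * (int(order) + 1)}, got {d}"
                )

    @property
    def n_samples(self) -> int:
        return self.features.shape[0]

    @property
    def n_features(self) -> int:
        return self.features.shape[1]

    def class_counts(self) -> tuple[int, int]:
        """(n_normal, n_braking)."""
        return int(np.sum(self.labels == LABEL_NORMAL)), int(
            np.sum(self.labels == LABEL_BRAKING)
        )
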