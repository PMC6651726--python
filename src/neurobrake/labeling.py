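"""IMU-driven event detection and automatic window labeling.

An executed braking event shows up in the IMU as a high-variance
transient: a 1-s window is event-positive when the standard deviation
of the 3-axis gyroscope magnitude exceeds 120 counts OR the 3-axis
accelerometer magnitude SD exceeds 12 counts.  Runs of positive windows
are collapsed to a single event timestamped at the first per-sample
threshold crossing.

EEG windows are then labeled against the detected events: a window
*ending* at time t is a braking-intention sample iff t lies in
``(e - pre_braking, e]`` for some event e (so the last braking window
ends exactly at the event); windows overlapping the 5 s after an event
are discarded (post-event instability); normal-driving windows must be
at least 5 s away from every event on both sides and quiet in the IMU.
Normal samples are subsampled (seeded) to at most twice the braking
count, keeping the class imbalance near the ~1.9:1 ratio of recorded
driving sessions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    LABEL_BRAKING,
    LABEL_NORMAL,
    LabeledSample,
    MultichannelWindow,
    SessionRecording,
)

_TIME_EPS = 1e-9


@dataclass
class LabelingConfig:
    """Thresholds and timing rules for automatic labeling."""

    gyro_sd_threshold: float = 120.0
    accel_sd_threshold: float = 12.0
    pre_braking_ms: float = 1000.0
    discard_after_s: float = 5.0
    min_event_separation_s: float = 5.0
    normal_margin_s: float = 5.0
    normal_subsample_ratio: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.gyro_sd_threshold <= 0 or self.accel_sd_threshold <= 0:
            raise ValueError("thresholds must be positive")
        if not 0 < self.pre_braking_ms <= 1000:
            raise ValueError("pre_braking_ms must be in (0, 1000]")
        if self.discard_after_s < 0 or self.min_event_separation_s < 0:
            raise ValueError("time rules must be non-negative")


def _magnitudes(imu: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """(accel magnitude, gyro magnitude) as vector norms over 3 axes."""
    imu = np.asarray(imu, dtype=np.float64)
    if imu.ndim != 2 or imu.shape[0] != 6:
        raise ValueError(f"imu must be 6 x N, got shape {imu.shape}")
    return (
        np.linalg.norm(imu[:3], axis=0),
        np.linalg.norm(imu[3:], axis=0),
    )


def _windowed_sd(x: np.ndarray, length: int, step: int) -> np.ndarray:
    """SD of x over windows [k*step, k*step + length)."""
    if x.size < length:
        return np.empty(0)
    views = np.lib.stride_tricks.sliding_window_view(x, length)[::step]
    return views.std(axis=1)


def imu_window_quiet(
    imu: np.ndarray, start: int, length: int, config: LabelingConfig
) -> bool:
    """True if the IMU magnitudes are sub-threshold within one window."""
    accel_mag, gyro_mag = _magnitudes(imu[:, start : start + length])
    return (
        gyro_mag.std() <= config.gyro_sd_threshold
        and accel_mag.std() <= config.accel_sd_threshold
    )


def detect_braking_events(
    imu: np.ndarray,
    fs: float = 128.0,
    window_s: float = 1.0,
    step_ms: float = 125.0,
    config: LabelingConfig | None = None,
) -> list[float]:
    """Detect executed braking events from the IMU streams.

    Slides a 1-s window at the given step; a window is event-positive
    when either sensor's magnitude SD exceeds its threshold.  Positive
    windows within ``min_event_separation_s`` of the previous event are
    absorbed into it; each new event is timestamped at the first sample
    of its first positive window whose absolute deviation from the
    window median exceeds the triggering threshold (falling back to the
    window start if no single sample crosses).

    Returns event times in seconds, sorted; an empty list is valid.
    """
    if config is None:
        config = LabelingConfig()
    length = int(round(window_s * fs))
    step = int(round(step_ms / 1000.0 * fs))
    if step <= 0:
        raise ValueError("step must be positive")
    accel_mag, gyro_mag = _magnitudes(imu)
    accel_sd = _windowed_sd(accel_mag, length, step)
    gyro_sd = _windowed_sd(gyro_mag, length, step)
    positive = (gyro_sd > config.gyro_sd_threshold) | (
        accel_sd > config.accel_sd_threshold
    )

    events: list[float] = []
    for k in np.flatnonzero(positive):
        start = k * step
        t_start = start / fs
        if events and t_start - events[-1] < config.min_event_separation_s:
            continue
        seg_a = accel_mag[start : start + length]
        seg_g = gyro_mag[start : start + length]
        crossing = None
        if gyro_sd[k] > config.gyro_sd_threshold:
            hits = np.flatnonzero(
                np.abs(seg_g - np.median(seg_g)) > config.gyro_sd_threshold
            )
            if hits.size:
                crossing = start + int(hits[0])
        if crossing is None and accel_sd[k] > config.accel_sd_threshold:
            hits = np.flatnonzero(
                np.abs(seg_a - np.median(seg_a)) > config.accel_sd_threshold
            )
            if hits.size:
                crossing = start + int(hits[0])
        events.append((crossing if crossing is not None else start) / fs)
    return events


def label_windows(
    windows: list[MultichannelWindow],
    events: list[float],
    config: LabelingConfig | None = None,
    session: SessionRecording | None = None,
) -> list[LabeledSample]:
    """Assign braking/normal labels to analysis windows.

    A window ending at t is labeled braking iff t is in
    ``(e - pre_braking, e]`` for some event e; windows overlapping
    ``(e, e + discard_after_s]`` are discarded; the remaining windows
    are normal candidates iff the whole window keeps at least
    ``normal_margin_s`` distance from every event and (when ``session``
    is given) its IMU magnitudes are sub-threshold.  Normal candidates
    are subsampled to at most ``normal_subsample_ratio`` times the
    braking count with the config seed, preserving temporal order.

    Label sets are disjoint by construction and the procedure is
    deterministic.
    """
    if config is None:
        config = LabelingConfig()
    pre_s = config.pre_braking_ms / 1000.0
    events = sorted(events)
    braking: list[LabeledSample] = []
    normal: list[LabeledSample] = []
    for idx, win in enumerate(windows):
        t0, t1 = win.start_time_s, win.end_time_s
        source = None
        for e in events:
            # half-open (e - P, e]: the last braking window ends at e
            if e - pre_s + _TIME_EPS < t1 <= e + _TIME_EPS:
                source = e
                break
        if source is not None:
            braking.append(
                LabeledSample(
                    label=LABEL_BRAKING,
                    window_end_s=t1,
                    window_index=idx,
                    source_event_s=source,
                )
            )
            continue
        if any(t1 > e + _TIME_EPS and t0 < e + config.discard_after_s for e in events):
            continue  # post-event instability: discard
        far = all(
            t1 <= e - config.normal_margin_s + _TIME_EPS
            or t0 >= e + config.normal_margin_s - _TIME_EPS
            for e in events
        )
        if not far:
            continue
        if session is not None:
            start = int(round(t0 * session.fs))
            if not imu_window_quiet(
                session.imu, start, win.n_samples, config
            ):
                continue
        normal.append(
            LabeledSample(label=LABEL_NORMAL, window_end_s=t1, window_index=idx)
        )

    ratio = config.normal_subsample_ratio
    max_normal = int(round(ratio * len(braking))) if np.isfinite(ratio) else len(normal)
    if braking and len(normal) > max_normal:
        rng = np.random.default_rng(config.seed)
        keep = np.sort(
            rng.choice(len(normal), size=max_normal, replace=False)
        )
        normal = [normal[i] for i in keep]
    out = braking + normal
    out.sort(key=lambda s: s.window_index)
    return out
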