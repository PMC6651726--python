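"""Glue: turn a session into a labeled feature table, and train
checkpointable classifiers, using the same per-window path as online
detection.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .core import DatasetTable, MultichannelWindow, SessionRecording
from .features import ar_features, band_power_features
from .labeling import LabelingConfig, detect_braking_events, label_windows
from .model import (
    Network,
    NetworkConfig,
    Standardizer,
    init_network,
    train,
)
from .preprocess import (
    DEFAULT_APEN_THRESHOLD,
    bandpass_filter,
    clean_window,
    segment_windows,
)


@dataclass
class PipelineConfig:
    """End-to-end configuration shared by training and online testing.

    ``use_ica`` switches per-window ICA + ApEn artifact censoring into
    the per-window path; it defaults to off because the generator's
    sessions contain no artifacts unless one is injected explicitly.
    """

    feature: str = "ar"  # "ar" | "bandpower"
    ar_order: int = 10
    step_ms: float = 125.0
    window_s: float = 1.0
    band_low_hz: float = 1.0
    band_high_hz: float = 60.0
    use_ica: bool = False
    apen_threshold: float = DEFAULT_APEN_THRESHOLD
    pre_braking_ms: float = 1000.0
    normal_ratio: float = 2.0
    n_hidden: int = 50
    max_iterations: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.feature not in ("ar", "bandpower"):
            raise ValueError("feature must be 'ar' or 'bandpower'")

    @property
    def n_features(self) -> int:
        return 40 if self.feature == "bandpower" else 8 * (self.ar_order + 1)

    def labeling_config(self) -> LabelingConfig:
        return LabelingConfig(
            pre_braking_ms=self.pre_braking_ms,
            normal_subsample_ratio=self.normal_ratio,
            seed=self.seed,
        )


def featurize_window(window: MultichannelWindow, config: PipelineConfig) -> np.ndarray:
    """Preprocess one raw window and extract its feature vector."""
    win = bandpass_filter(window, config.band_low_hz, config.band_high_hz)
    if config.use_ica:
        win = clean_window(win, config.apen_threshold, seed=config.seed)
    if config.feature == "bandpower":
        return band_power_features(win).vector
    return ar_features(win, config.ar_order).vector


def build_dataset(
    session: SessionRecording,
    config: PipelineConfig | None = None,
    events: list[float] | None = None,
) -> DatasetTable:
    """Segment, IMU-label, and featurize one session.

    Events default to IMU detection at the same step size used for the
    EEG windows; pass ``events`` to override (e.g. ground truth).
    """
    if config is None:
        config = PipelineConfig()
    windows = segment_windows(session, config.window_s, config.step_ms)
    if events is None:
        events = detect_braking_events(
            session.imu,
            fs=session.fs,
            window_s=config.window_s,
            step_ms=config.step_ms,
            config=config.labeling_config(),
        )
    samples = label_windows(
        windows, events, config.labeling_config(), session=session
    )
    feats = np.array(
        [featurize_window(windows[s.window_index], config) for s in samples]
    )
    labels = np.array([s.label for s in samples])
    ends = np.array([s.window_end_s for s in samples])
    if feats.size == 0:
        feats = feats.reshape(0, config.n_features)
    # Provenance groups for leakage-safe cross-validation: overlapping
    # windows of one braking event (or of one quiet segment between
    # events) always land in the same CV fold.
    ev = np.asarray(sorted(events))
    groups = np.empty(len(samples), dtype=np.int64)
    for i, s in enumerate(samples):
        if s.source_event_s is not None:
            groups[i] = 2 * int(np.searchsorted(ev, s.source_event_s))
        else:
            groups[i] = 2 * int(np.searchsorted(ev, s.window_end_s)) + 1
    return DatasetTable(
        features=feats,
        labels=labels,
        meta={
            "feature": config.feature,
            "ar_order": config.ar_order if config.feature == "ar" else None,
            "step_ms": config.step_ms,
            "pre_braking_ms": config.pre_braking_ms,
        },
        window_end_s=ends,
        groups=groups,
    )


def fit_classifier(
    train_table: DatasetTable,
    val_table: DatasetTable | None = None,
    config: PipelineConfig | None = None,
) -> tuple[Network, Standardizer]:
    """Standardize on the training table and train an MLP."""
    if config is None:
        config = PipelineConfig()
    std = Standardizer().fit(train_table.features)
    xt = std.transform(train_table.features)
    val = None
    if val_table is not None:
        val = (std.transform(val_table.features), val_table.labels)
    net = init_network(
        NetworkConfig(
            n_input=train_table.n_features,
            n_hidden=config.n_hidden,
            max_iterations=config.max_iterations,
            seed=config.seed,
        )
    )
    train(net, (xt, train_table.labels), val)
    return net, std


def with_params(config: PipelineConfig, **kwargs) -> PipelineConfig:
    """A copy of ``config`` with the given fields replaced."""
    return replace(config, **kwargs)
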