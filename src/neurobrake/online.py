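"""Simulated real-time detection on a rolling 1-s buffer.

The stream advances in step-size chunks (8/16/32 samples for
62.5/125/250 ms); after the 1-s warm-up the buffer always holds exactly
128 samples and one prediction is made per step on the same
preprocess -> featurize -> predict path used in training, so streaming
output is bit-identical to batch segmentation at the same step size.
A detection fires after ``smoothing_n`` consecutive braking
predictions (debounce); its lead time is measured against the next
executed braking event (positive = the detection precedes braking).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LABEL_BRAKING, MultichannelWindow, SessionRecording
from .labeling import LabelingConfig, detect_braking_events, label_windows
from .model import Network, Standardizer, predict
from .pipeline import PipelineConfig, featurize_window
from .preprocess import segment_windows


@dataclass
class DetectionEvent:
    detection_time_s: float
    braking_event_s: float | None = None

    @property
    def lead_time_ms(self) -> float | None:
        """Positive when the detection precedes the braking event."""
        if self.braking_event_s is None:
            return None
        return (self.braking_event_s - self.detection_time_s) * 1000.0


@dataclass
class StreamResult:
    times_s: np.ndarray  # prediction times (window ends), on the step grid
    labels: np.ndarray  # per-step predicted class
    scores: np.ndarray  # per-step braking probability
    detections: list[DetectionEvent] = field(default_factory=list)


def stream_detect(
    session: SessionRecording,
    net: Network,
    standardizer: Standardizer,
    config: PipelineConfig | None = None,
    smoothing_n: int = 3,
    detection_threshold: float = 0.95,
    events: list[float] | None = None,
    association_window_s: float = 1.5,
) -> StreamResult:
    """Run the classifier over a session as an online stream.

    The first prediction is made at t = 1 s (full buffer) and then
    every ``config.step_ms``.  Per-step labels are the plain argmax of
    the softmax output (identical to batch classification); a
    :class:`DetectionEvent` additionally requires confidence — it fires
    at the ``smoothing_n``-th consecutive step whose braking
    probability exceeds ``detection_threshold`` (debounce against
    isolated false positives) — and is associated with the nearest
    braking event within ``association_window_s`` on either side
    (IMU-detected by default, ground truth if ``events`` is given); at
    most one detection fires per braking episode.

    Raises
    ------
    ValueError
        If the step is not a whole number of samples or the session is
        shorter than one buffer.
    """
    if config is None:
        config = PipelineConfig()
    fs = session.fs
    step_samples = config.step_ms / 1000.0 * fs
    if abs(step_samples - round(step_samples)) > 1e-9 or step_samples <= 0:
        raise ValueError("step must be a positive whole number of samples")
    step = int(round(step_samples))
    buffer_len = int(round(config.window_s * fs))
    if session.n_samples < buffer_len:
        raise ValueError("session shorter than one analysis buffer")
    if events is None:
        events = detect_braking_events(
            session.imu,
            fs=fs,
            window_s=config.window_s,
            step_ms=config.step_ms,
            config=config.labeling_config(),
        )
    events_arr = np.asarray(sorted(events))

    times, feats = [], []
    buffer = np.empty((8, buffer_len))
    for end in range(buffer_len, session.n_samples + 1, step):
        buffer[:] = session.eeg[:, end - buffer_len : end]
        window = MultichannelWindow(
            samples=buffer, start_time_s=end / fs - config.window_s, fs=fs
        )
        feats.append(featurize_window(window, config))
        times.append(end / fs)
    times = np.asarray(times)
    labels, scores = predict(net, standardizer.transform(np.asarray(feats)))

    detections: list[DetectionEvent] = []
    run = 0
    last_assoc: float | None = None
    for t_end, label, score in zip(times, labels, scores):
        confident = label == LABEL_BRAKING and score > detection_threshold
        run = run + 1 if confident else 0
        if run == smoothing_n:
            assoc = None
            if events_arr.size:
                j = int(np.argmin(np.abs(events_arr - t_end)))
                if abs(events_arr[j] - t_end) <= association_window_s:
                    assoc = float(events_arr[j])
            if assoc is not None and assoc == last_assoc:
                pass  # this braking episode was already reported
            else:
                detections.append(
                    DetectionEvent(
                        detection_time_s=float(t_end), braking_event_s=assoc
                    )
                )
                last_assoc = assoc
    return StreamResult(
        times_s=times,
        labels=np.asarray(labels, dtype=int),
        scores=np.asarray(scores),
        detections=detections,
    )


@dataclass
class OnlineReport:
    step_accuracy: float | None
    event_recall: float | None
    mean_lead_time_ms: float | None
    false_alarms: int
    n_events: int
    n_steps_scored: int


def evaluate_online(
    result: StreamResult,
    session: SessionRecording,
    config: PipelineConfig | None = None,
    events: list[float] | None = None,
) -> OnlineReport:
    """Score a streaming run against the training labeling rules.

    Per-step accuracy uses the same braking/discard/normal rules as
    training (unlabelable steps are excluded); event recall is the
    fraction of braking events preceded by an associated detection with
    positive lead time; false alarms are detections associated with no
    event.  With no events in the session the event-level metrics are
    ``None``.
    """
    if config is None:
        config = PipelineConfig()
    if events is None:
        events = detect_braking_events(
            session.imu,
            fs=session.fs,
            window_s=config.window_s,
            step_ms=config.step_ms,
            config=config.labeling_config(),
        )
    lcfg = config.labeling_config()
    # reference labels on the same step grid, without subsampling
    ref_cfg = LabelingConfig(
        pre_braking_ms=lcfg.pre_braking_ms,
        normal_subsample_ratio=np.inf,
        seed=lcfg.seed,
    )
    windows = segment_windows(session, config.window_s, config.step_ms)
    ref = label_windows(windows, events, ref_cfg, session=session)
    by_end = {round(s.window_end_s * session.fs): s.label for s in ref}
    y_true, y_pred = [], []
    for t, lab in zip(result.times_s, result.labels):
        key = round(t * session.fs)
        if key in by_end:
            y_true.append(by_end[key])
            y_pred.append(lab)
    acc = (
        float(np.mean(np.asarray(y_true) == np.asarray(y_pred)))
        if y_true
        else None
    )

    if not events:
        return OnlineReport(
            step_accuracy=acc,
            event_recall=None,
            mean_lead_time_ms=None,
            false_alarms=sum(
                1 for d in result.detections if d.braking_event_s is None
            ),
            n_events=0,
            n_steps_scored=len(y_true),
        )
    hits = {}
    for d in result.detections:
        if d.braking_event_s is None:
            continue
        lead = d.lead_time_ms
        if lead is not None and lead >= 0 and d.braking_event_s not in hits:
            hits[d.braking_event_s] = lead
    recall = len(hits) / len(events)
    mean_lead = float(np.mean(list(hits.values()))) if hits else None
    false_alarms = sum(1 for d in result.detections if d.braking_event_s is None)
    return OnlineReport(
        step_accuracy=acc,
        event_recall=recall,
        mean_lead_time_ms=mean_lead,
        false_alarms=false_alarms,
        n_events=len(events),
        n_steps_scored=len(y_true),
    )
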