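"""Read/write driving sessions and labeled datasets.

Native container is HDF5 with the layout::

    /eeg      float64 (8, N)   microvolts
    /imu      float64 (6, N)   accelerometer + gyroscope counts
    /events   float64 (k, 2)   [stimulus_time_s, braking_time_s] (optional)
    attrs:    fs (Hz), channel_names, schema = "neurobrake-session-1"

Datasets (feature tables) use::

    /features float64 (M, D)
    /labels   int64   (M,)
    /window_end_s float64 (M,)  (optional)
    attrs:    schema = "neurobrake-dataset-1" + flat meta keys

EDF export is provided for EEG interoperability with standard viewers;
only the 8 EEG channels are written (EDF carries no paired IMU/event
payload).  The writer emits plain EDF: a 256-byte fixed header,
256 bytes per signal, then 1-s data records of little-endian 16-bit
integers scaled channel-wise to the physical range.
"""

from __future__ import annotations

import numpy as np

from .core import DatasetTable, SessionRecording

SESSION_SCHEMA = "neurobrake-session-1"
DATASET_SCHEMA = "neurobrake-dataset-1"


class SchemaError(ValueError):
    """File does not match the expected on-disk schema."""


def write_session(session: SessionRecording, path) -> None:
    """Write a session to the native HDF5 container."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["schema"] = SESSION_SCHEMA
        f.attrs["fs"] = float(session.fs)
        f.attrs["channel_names"] = [str(c) for c in session.channel_names]
        f.create_dataset("eeg", data=session.eeg)
        f.create_dataset("imu", data=session.imu)
        if session.truth_events is not None:
            f.create_dataset(
                "events", data=np.asarray(session.truth_events, dtype=np.float64).reshape(-1, 2)
            )


def read_session(path) -> SessionRecording:
    """Read a session written by :func:`write_session`.

    Raises
    ------
    SchemaError
        Naming the missing/invalid field when the file is malformed.
    """
    import h5py

    with h5py.File(path, "r") as f:
        for key in ("eeg", "imu"):
            if key not in f:
                raise SchemaError(f"missing dataset '/{key}'")
        for attr in ("fs", "channel_names"):
            if attr not in f.attrs:
                raise SchemaError(f"missing attribute '{attr}'")
        eeg = f["eeg"][()]
        imu = f["imu"][()]
        if eeg.ndim != 2 or eeg.shape[0] != 8:
            raise SchemaError(f"expected 8 EEG channels, got shape {eeg.shape}")
        if imu.ndim != 2 or imu.shape[0] != 6:
            raise SchemaError(f"expected 6 IMU channels, got shape {imu.shape}")
        events = None
        if "events" in f:
            arr = f["events"][()]
            events = [(float(s), float(b)) for s, b in arr]
        names = tuple(
            c.decode() if isinstance(c, bytes) else str(c)
            for c in f.attrs["channel_names"]
        )
        return SessionRecording(
            eeg=eeg,
            imu=imu,
            fs=float(f.attrs["fs"]),
            channel_names=names,
            truth_events=events,
        )


def write_dataset(table: DatasetTable, path) -> None:
    """Write a labeled feature table to HDF5."""
    import h5py

    with h5py.File(path, "w") as f:
        f.attrs["schema"] = DATASET_SCHEMA
        for k, v in table.meta.items():
            if v is not None:
                f.attrs[f"meta_{k}"] = v
        f.create_dataset("features", data=table.features)
        f.create_dataset("labels", data=table.labels)
        if table.window_end_s is not None:
            f.create_dataset("window_end_s", data=np.asarray(table.window_end_s))


def read_dataset(path) -> DatasetTable:
    import h5py

    with h5py.File(path, "r") as f:
        for key in ("features", "labels"):
            if key not in f:
                raise SchemaError(f"missing dataset '/{key}'")
        meta = {
            k[len("meta_"):]: (v.item() if hasattr(v, "item") else v)
            for k, v in f.attrs.items()
            if k.startswith("meta_")
        }
        meta = {
            k: (v.decode() if isinstance(v, bytes) else v) for k, v in meta.items()
        }
        ends = f["window_end_s"][()] if "window_end_s" in f else None
        return DatasetTable(
            features=f["features"][()],
            labels=f["labels"][()],
            meta=meta,
            window_end_s=ends,
        )


def _edf_field(value, width: int) -> bytes:
    s = str(value)[:width]
    return s.ljust(width).encode("ascii")


def export_eeg_edf(session: SessionRecording, path) -> None:
    """Export the 8 EEG channels as a plain EDF file at the session rate.

    Samples are quantized to 16-bit integers over each channel's
    physical range, so re-imported data match the original up to that
    quantization (per-channel correlation > 0.999 in practice).
    """
    if session.n_samples == 0:
        raise ValueError("cannot export an empty session")
    fs = session.fs
    spr = int(round(fs))  # samples per 1-s data record, per signal
    n_rec = session.n_samples // spr
    if n_rec == 0:
        raise ValueError("session shorter than one EDF data record (1 s)")
    ns = 8
    data = session.eeg[:, : n_rec * spr]

    phys_min = np.floor(data.min(axis=1))
    phys_max = np.ceil(data.max(axis=1))
    flat = phys_max <= phys_min
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    header = b"".join(
        [
            _edf_field("0", 8),  # version
            _edf_field("X X X X", 80),  # patient id (anonymous)
            _edf_field("Startdate X neurobrake", 80),  # recording id
            _edf_field("01.01.00", 8),
            _edf_field("00.00.00", 8),
            _edf_field(256 + 256 * ns, 8),  # header bytes
            _edf_field("", 44),  # reserved
            _edf_field(n_rec, 8),
            _edf_field("1", 8),  # record duration (s)
            _edf_field(ns, 4),
        ]
    )
    labels = b"".join(_edf_field(f"EEG {c}", 16) for c in session.channel_names)
    transducer = b"".join(_edf_field("AgAgCl electrode", 80) for _ in range(ns))
    dim = b"".join(_edf_field("uV", 8) for _ in range(ns))
    pmin = b"".join(_edf_field(f"{v:.1f}", 8) for v in phys_min)
    pmax = b"".join(_edf_field(f"{v:.1f}", 8) for v in phys_max)
    dmin = b"".join(_edf_field(dig_min, 8) for _ in range(ns))
    dmax = b"".join(_edf_field(dig_max, 8) for _ in range(ns))
    prefilter = b"".join(_edf_field("", 80) for _ in range(ns))
    n_samp = b"".join(_edf_field(spr, 8) for _ in range(ns))
    reserved = b"".join(_edf_field("", 32) for _ in range(ns))

    # channel-wise linear map physical -> digital
    gain = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * gain[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with open(path, "wb") as f:
        f.write(header)
        f.write(labels + transducer + dim + pmin + pmax + dmin + dmax
                + prefilter + n_samp + reserved)
        for r in range(n_rec):
            block = digital[:, r * spr : (r + 1) * spr]  # (8, spr)
            f.write(block.tobytes())  # signal-major within record
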