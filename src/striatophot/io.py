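"""Session data model and tabular I/O.

The canonical interchange format is CSV. A photometry session lives in
three sibling files:

``<stem>.csv``
    Columns ``time_s, signal, reference`` (floats). ``signal`` is the
    demodulated fluorescence of the sensor channel (465 nm GCaMP8s or
    560 nm rDA3m) and ``reference`` the 405 nm UV isosbestic channel,
    both sampled uniformly (nominally 1 kHz).
``<stem>.events.csv``
    Columns ``label, onset_s, offset_s``; ``offset_s`` is blank for point
    events. Interval events (e.g. "stim") carry both columns.
``<stem>.meta.json``
    Free-form metadata plus the sensor kind (``gcamp`` or ``rdam``).

Velocity traces use ``time_s, velocity_cm_s`` (or ``time_s, volts`` before
encoder calibration). Time is in seconds, zero-based at session start; all
analysis windows downstream are half-open ``[start, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError, SamplingError, SchemaError

#: relative tolerance on the uniformity of the time step
TIME_STEP_RTOL = 1e-9

#: rotary encoder calibration point: 10 cm/s at 2.5 V
DEFAULT_ENCODER_CALIBRATION = (10.0, 2.5)


def _check_time_base(time: np.ndarray, where: str) -> float:
    """Validate a strictly increasing, uniform time base; return the step."""
    if time.ndim != 1 or time.size < 2:
        raise DataError(f"{where}: need at least 2 samples")
    steps = np.diff(time)
    step = float(np.median(steps))
    if step <= 0 or np.any(steps <= 0):
        raise SamplingError(f"{where}: time must be strictly increasing")
    dev = float(np.max(np.abs(steps - step)))
    if dev > TIME_STEP_RTOL * max(step, abs(float(time[-1]))):
        raise SamplingError(
            f"{where}: non-uniform time step (median {step:.9g} s, "
            f"max deviation {dev:.3g} s, min {steps.min():.9g}, max {steps.max():.9g})")
    return step


def _check_finite(arr: np.ndarray, name: str) -> None:
    bad = ~np.isfinite(arr)
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise DataError(f"non-finite value in '{name}' at row {idx}")


@dataclass
class EventTrain:
    """A labelled train of events, optionally with offsets (interval events)."""

    label: str
    onsets: np.ndarray
    offsets: Optional[np.ndarray] = None

    def __post_init__(self):
        self.onsets = np.asarray(self.onsets, dtype=float)
        if self.offsets is not None:
            self.offsets = np.asarray(self.offsets, dtype=float)

    def validate(self, t0: float, t1: float) -> None:
        if np.any(np.diff(self.onsets) < 0):
            raise DataError(f"event train '{self.label}': onsets not sorted")
        if self.onsets.size and (self.onsets[0] < t0 or self.onsets[-1] > t1):
            raise DataError(f"event train '{self.label}': onset outside session")
        if self.offsets is not None:
            if self.offsets.shape != self.onsets.shape:
                raise DataError(f"event train '{self.label}': onset/offset length mismatch")
            if np.any(self.offsets <= self.onsets):
                raise DataError(f"event train '{self.label}': offsets must follow onsets")
            if np.any(self.onsets[1:] < self.offsets[:-1]):
                raise DataError(f"event train '{self.label}': overlapping intervals")
            if self.offsets.size and self.offsets[-1] > t1:
                raise DataError(f"event train '{self.label}': offset outside session")


@dataclass
class PhotometrySession:
    """Demodulated two-channel photometry recording on a uniform time base."""

    time: np.ndarray
    signal: np.ndarray
    reference: np.ndarray
    sampling_rate: float
    sensor_kind: str = "gcamp"
    events: list = field(default_factory=list)
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        self.reference = np.asarray(self.reference, dtype=float)

    @property
    def duration_s(self) -> float:
        return self.time.size / self.sampling_rate

    def validate(self) -> None:
        if self.sensor_kind not in ("gcamp", "rdam"):
            raise ParameterError(f"unknown sensor_kind '{self.sensor_kind}'")
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if not (self.time.shape == self.signal.shape == self.reference.shape):
            raise DataError("time, signal and reference must have equal length")
        step = _check_time_base(self.time, "session")
        if abs(step * self.sampling_rate - 1.0) > 1e-6:
            raise SamplingError(
                f"sampling_rate {self.sampling_rate} Hz inconsistent with "
                f"time step {step:.9g} s")
        _check_finite(self.signal, "signal")
        _check_finite(self.reference, "reference")
        for train in self.events:
            train.validate(float(self.time[0]), float(self.time[-1]))

    def event_train(self, label: str) -> EventTrain:
        for train in self.events:
            if train.label == label:
                return train
        raise KeyError(f"no event train labelled '{label}'")


@dataclass
class VelocityTrace:
    """Calibrated velocity time series (cm/s, signed; sign = direction)."""

    time: np.ndarray
    velocity: np.ndarray
    sampling_rate: float

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)

    @property
    def duration_s(self) -> float:
        return self.time.size / self.sampling_rate

    def validate(self) -> None:
        if self.sampling_rate <= 0:
            raise ParameterError("sampling_rate must be > 0")
        if self.time.shape != self.velocity.shape:
            raise DataError("time and velocity must have equal length")
        _check_time_base(self.time, "velocity trace")
        _check_finite(self.velocity, "velocity")


# ---------------------------------------------------------------------------
# CSV reading / writing
# ---------------------------------------------------------------------------

_FLOAT_FMT = "%.17g"  # lossless round-trip for float64


def _companion_paths(path) -> tuple[Path, Path]:
    p = Path(path)
    return (p.with_name(p.stem + ".events.csv"),
            p.with_name(p.stem + ".meta.json"))


def read_session(path, config=None) -> PhotometrySession:
    """Read a photometry session from ``<stem>.csv`` and its companions.

    Raises :class:`SchemaError` on missing columns, :class:`SamplingError`
    on a non-uniform time base and :class:`DataError` on NaN values.
    """
    df = pd.read_csv(path)
    missing = [c for c in ("time_s", "signal", "reference") if c not in df.columns]
    if missing:
        raise SchemaError(f"session file {path}: missing column(s) {missing}")
    time = df["time_s"].to_numpy(dtype=float)
    signal = df["signal"].to_numpy(dtype=float)
    reference = df["reference"].to_numpy(dtype=float)
    _check_finite(signal, "signal")
    _check_finite(reference, "reference")
    step = _check_time_base(time, f"session file {path}")

    events_path, meta_path = _companion_paths(path)
    events: list[EventTrain] = []
    if events_path.exists():
        events = _read_events(events_path)
    meta: dict = {}
    sensor_kind = "gcamp"
    if meta_path.exists():
        with open(meta_path, "r", encoding="utf-8") as fh:
            meta = json.load(fh)
        sensor_kind = meta.pop("sensor_kind", sensor_kind)

    session = PhotometrySession(time=time, signal=signal, reference=reference,
                                sampling_rate=1.0 / step, sensor_kind=sensor_kind,
                                events=events, meta=meta)
    session.validate()
    return session


def write_session(session: PhotometrySession, path) -> None:
    """Write a session (and companions) so that :func:`read_session` recovers it."""
    session.validate()
    df = pd.DataFrame({"time_s": session.time, "signal": session.signal,
                       "reference": session.reference})
    df.to_csv(path, index=False, float_format=_FLOAT_FMT)
    events_path, meta_path = _companion_paths(path)
    if session.events:
        _write_events(session.events, events_path)
    meta = dict(session.meta)
    meta["sensor_kind"] = session.sensor_kind
    with open(meta_path, "w", encoding="utf-8") as fh:
        json.dump(meta, fh, sort_keys=True, indent=1, default=float)
        fh.write("\n")


def _read_events(path) -> list[EventTrain]:
    df = pd.read_csv(path)
    missing = [c for c in ("label", "onset_s") if c not in df.columns]
    if missing:
        raise SchemaError(f"events file {path}: missing column(s) {missing}")
    trains = []
    for label, grp in df.groupby("label", sort=False):
        onsets = grp["onset_s"].to_numpy(dtype=float)
        offsets = None
        if "offset_s" in grp.columns and grp["offset_s"].notna().all():
            offsets = grp["offset_s"].to_numpy(dtype=float)
        trains.append(EventTrain(label=str(label), onsets=onsets, offsets=offsets))
    return trains


def _write_events(events: list, path) -> None:
    rows = []
    for train in events:
        offs = train.offsets if train.offsets is not None else [np.nan] * train.onsets.size
        for on, off in zip(train.onsets, offs):
            rows.append({"label": train.label, "onset_s": on, "offset_s": off})
    pd.DataFrame(rows, columns=["label", "onset_s", "offset_s"]).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def read_velocity(path, config=None) -> VelocityTrace:
    """Read a velocity CSV (``time_s, velocity_cm_s`` or ``time_s, volts``).

    A ``volts`` column is converted through the encoder calibration in
    ``config`` (default 4 cm/s per volt, i.e. 10 cm/s at 2.5 V).
    """
    df = pd.read_csv(path)
    if "time_s" not in df.columns:
        raise SchemaError(f"velocity file {path}: missing column(s) ['time_s']")
    time = df["time_s"].to_numpy(dtype=float)
    step = _check_time_base(time, f"velocity file {path}")
    if "velocity_cm_s" in df.columns:
        vel = df["velocity_cm_s"].to_numpy(dtype=float)
    elif "volts" in df.columns:
        factor = 4.0 if config is None else config.encoder_cm_s_per_volt
        vel = df["volts"].to_numpy(dtype=float) * factor
    else:
        raise SchemaError(
            f"velocity file {path}: missing column(s) ['velocity_cm_s' or 'volts']")
    _check_finite(vel, "velocity")
    trace = VelocityTrace(time=time, velocity=vel, sampling_rate=1.0 / step)
    trace.validate()
    return trace


def write_velocity(trace: VelocityTrace, path) -> None:
    trace.validate()
    pd.DataFrame({"time_s": trace.time, "velocity_cm_s": trace.velocity}).to_csv(
        path, index=False, float_format=_FLOAT_FMT)


def encoder_to_velocity(volts: np.ndarray, sampling_rate: float,
                        calibration: tuple = DEFAULT_ENCODER_CALIBRATION,
                        t0: float = 0.0) -> VelocityTrace:
    """Convert rotary-encoder voltage to velocity.

    The encoder output is linear through zero; the calibration pair
    ``(speed_cm_s, volts)`` defaults to (10, 2.5), i.e. 4 cm/s per volt.
    Negative voltage (backward walking) maps to negative velocity.
    """
    speed, cal_volts = calibration
    if speed <= 0 or cal_volts <= 0:
        raise ParameterError("encoder calibration must be positive (speed, volts)")
    volts = np.asarray(volts, dtype=float)
    _check_finite(volts, "volts")
    velocity = volts * (speed / cal_volts)
    time = t0 + np.arange(volts.size) / float(sampling_rate)
    return VelocityTrace(time=time, velocity=velocity, sampling_rate=float(sampling_rate))
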