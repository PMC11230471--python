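"""Event-aligned activity and stimulation-locked dopamine metrics.

`align` slices a normalized trace around behavioral or stimulation events
onto a common relative-time grid (trial x time matrix). Locomotion analyses
align the z-scored ΔF/F; stimulation dopamine metrics use raw ΔF/F.

Timing and slope statistics around locomotion events:

* time of maximum activity within 1 s before to 1 s after the event
  (closed window; ties resolve to the earliest time);
* slope of a least-squares line on the z-scored activity from 0.5 s before
  to 0.5 s after locomotion offset.

Stimulation metrics per trial, each relative to the trial baseline (mean
ΔF/F over the 2 s preceding onset):

* reduction: mean ΔF/F over the 0.2 s before stimulus offset;
* onset peak: mean ΔF/F over 0.35-0.45 s after onset;
* post-stimulus change: mean ΔF/F over 3-8 s after offset.

Amplitudes are signed as ``window_mean - baseline`` so suppression is
negative and the onset peak positive, matching the one-sample left-/right-
tailed tests applied downstream; a config flag restores the literal
``baseline - window`` orientation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

from .config import PerieventConfig, StimWindowConfig
from .errors import DataError, ParameterError
from .io import EventTrain
from .photometry import NormalizedTrace


@dataclass
class PeriEventMatrix:
    """Trial x time matrix of event-aligned activity."""

    values: np.ndarray  # (n_trials, n_time)
    rel_time: np.ndarray  # seconds relative to the event (0 = event)
    event_kind: str
    trial_ids: np.ndarray
    n_dropped: int = 0
    empty: bool = False

    def mean_trace(self) -> np.ndarray:
        return self.values.mean(axis=0)


@dataclass
class OffsetStats:
    """Session-level timing and slope statistics around locomotion events."""

    t_max_onset: float
    t_max_offset: float
    offset_slope: float
    n_onsets: int
    n_offsets: int


def _as_trace(trace: Union[NormalizedTrace, np.ndarray], use: str):
    if isinstance(trace, NormalizedTrace):
        arr = getattr(trace, use)
        return np.asarray(arr, dtype=float), trace.sampling_rate, float(trace.time[0])
    raise TypeError("pass a NormalizedTrace, or use align_array for raw arrays")


def align_array(trace: np.ndarray, sampling_rate: float,
                event_times: Sequence[float], window: tuple = (-2.0, 2.0),
                rel_fs: Optional[float] = None, event_kind: str = "event",
                t0: float = 0.0) -> PeriEventMatrix:
    """Align a uniformly sampled trace to events on a relative-time grid.

    Events whose window extends beyond the trace are dropped (counted in
    ``n_dropped``). Zero usable events yields an empty matrix with
    ``empty=True`` rather than an exception. Rows are linear interpolations
    of the trace at ``event + rel_time``.
    """
    trace = np.asarray(trace, dtype=float)
    pre, post = window
    if not pre < post:
        raise ParameterError("alignment window must be increasing")
    fs = rel_fs if rel_fs is not None else sampling_rate
    n_rel = int(round((post - pre) * fs)) + 1
    rel_time = pre + np.arange(n_rel) / fs
    time = t0 + np.arange(trace.size) / sampling_rate
    tol = 0.5 / sampling_rate

    rows, kept = [], []
    dropped = 0
    for i, ev in enumerate(np.asarray(event_times, dtype=float)):
        if ev + pre < time[0] - tol or ev + post > time[-1] + tol:
            dropped += 1
            continue
        rows.append(np.interp(ev + rel_time, time, trace))
        kept.append(i)
    if not rows:
        return PeriEventMatrix(values=np.empty((0, n_rel)), rel_time=rel_time,
                               event_kind=event_kind,
                               trial_ids=np.empty(0, dtype=int),
                               n_dropped=dropped, empty=True)
    return PeriEventMatrix(values=np.vstack(rows), rel_time=rel_time,
                           event_kind=event_kind,
                           trial_ids=np.asarray(kept, dtype=int),
                           n_dropped=dropped)


def align(norm: NormalizedTrace, event_times: Sequence[float],
          window: tuple = (-2.0, 2.0), use: str = "zscore",
          rel_fs: Optional[float] = None,
          event_kind: str = "event") -> PeriEventMatrix:
    """Align a normalized trace (``use`` = ``zscore`` or ``dff``) to events."""
    arr, fs, t0 = _as_trace(norm, use)
    return align_array(arr, fs, event_times, window=window, rel_fs=rel_fs,
                       event_kind=event_kind, t0=t0)


def max_timing(matrix: PeriEventMatrix, search: tuple = (-1.0, 1.0)):
    """Time of maximum of the trial-mean trace within the closed search window.

    Returns ``(session_t_max, per_trial_t_max)``. Ties resolve to the
    earliest time in the window, so a flat trace reports the window start.
    """
    a, b = search
    mask = (matrix.rel_time >= a) & (matrix.rel_time <= b)
    if not mask.any():
        raise ParameterError("search window outside the aligned time span")
    rel = matrix.rel_time[mask]
    if matrix.empty:
        return float("nan"), np.empty(0)
    session = float(rel[np.argmax(matrix.mean_trace()[mask])])
    per_trial = rel[np.argmax(matrix.values[:, mask], axis=1)]
    return session, per_trial


def offset_slope(matrix: PeriEventMatrix, window: tuple = (-0.5, 0.5)) -> float:
    """Least-squares slope of the trial-mean trace on the half-open window.

    Units are activity units per second (z-units/s when the matrix holds
    z-scored ΔF/F).
    """
    a, b = window
    mask = (matrix.rel_time >= a) & (matrix.rel_time < b)
    if mask.sum() < 3:
        raise ParameterError("slope window holds fewer than 3 samples")
    if matrix.empty:
        return float("nan")
    x = matrix.rel_time[mask]
    y = matrix.mean_trace()[mask]
    return float(np.polyfit(x, y, 1)[0])


def session_offset_stats(norm: NormalizedTrace, onsets: Sequence[float],
                         offsets: Sequence[float],
                         config: Optional[PerieventConfig] = None) -> OffsetStats:
    """Timing-of-maximum (onset and offset) and pre-offset slope for a session."""
    cfg = config or PerieventConfig()
    mat_on = align(norm, onsets, window=cfg.locomotion_window_s, use="zscore",
                   event_kind="locomotion_onset")
    mat_off = align(norm, offsets, window=cfg.locomotion_window_s, use="zscore",
                    event_kind="locomotion_offset")
    t_on, _ = max_timing(mat_on, cfg.max_search_s)
    t_off, _ = max_timing(mat_off, cfg.max_search_s)
    slope = offset_slope(mat_off, cfg.slope_window_s) if not mat_off.empty else float("nan")
    return OffsetStats(t_max_onset=t_on, t_max_offset=t_off, offset_slope=slope,
                       n_onsets=int(mat_on.values.shape[0]),
                       n_offsets=int(mat_off.values.shape[0]))


def _window_mean(trace: np.ndarray, time: np.ndarray, a: float, b: float) -> float:
    i0 = int(np.searchsorted(time, a, side="left"))
    i1 = int(np.searchsorted(time, b, side="left"))
    if i1 <= i0:
        return float("nan")
    return float(np.mean(trace[i0:i1]))


def stim_metrics(norm: NormalizedTrace, stim: EventTrain,
                 windows: Optional[StimWindowConfig] = None,
                 durations: tuple = (2.0, 5.0, 15.0),
                 literal_sign: bool = False,
                 frequency_label: str = "") -> pd.DataFrame:
    """Per-trial stimulation-locked dopamine amplitudes (ΔF/F units).

    One row per usable trial with ``baseline_dff`` and the three
    baseline-subtracted amplitudes; trials whose analysis windows extend
    past the session are dropped and counted in ``df.attrs['n_dropped']``.
    Trials are grouped by the nearest protocol duration.
    """
    if norm.chain != "rdam":
        raise ParameterError("stim_metrics requires the rdam chain (raw ΔF/F)")
    if stim.offsets is None:
        raise DataError("stimulation events need offsets (interval events)")
    w = windows or StimWindowConfig()
    w.validate()
    dff = np.asarray(norm.dff, dtype=float)
    time = np.asarray(norm.time, dtype=float)
    t_lo, t_hi = float(time[0]), float(time[-1])
    sign = -1.0 if literal_sign else 1.0

    rows = []
    dropped = 0
    for i, (on, off) in enumerate(zip(stim.onsets, stim.offsets)):
        lo = on - w.baseline_pre_s
        hi = off + w.post_window_s[1]
        if lo < t_lo or hi > t_hi + 0.5 / norm.sampling_rate:
            dropped += 1
            continue
        baseline = _window_mean(dff, time, on - w.baseline_pre_s, on)
        red = _window_mean(dff, time, off - w.reduction_pre_s, off)
        peak = _window_mean(dff, time, on + w.peak_window_s[0], on + w.peak_window_s[1])
        post = _window_mean(dff, time, off + w.post_window_s[0],
                            off + w.post_window_s[1])
        dur = durations[int(np.argmin([abs((off - on) - d) for d in durations]))] \
            if durations else off - on
        rows.append({
            "trial": i, "stim_duration_s": float(dur),
            "stim_frequency": frequency_label,
            "baseline_dff": baseline,
            "reduction_amp": sign * (red - baseline),
            "peak_amp": sign * (peak - baseline),
            "post_stim_amp": sign * (post - baseline),
        })
    df = pd.DataFrame(rows, columns=["trial", "stim_duration_s", "stim_frequency",
                                     "baseline_dff", "reduction_amp", "peak_amp",
                                     "post_stim_amp"])
    df.attrs["n_dropped"] = dropped
    return df
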