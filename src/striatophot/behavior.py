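"""Bout segmentation of velocity and activity traces.

Three taxonomies are implemented:

* treadmill movement/rest: a 0.25 cm/s threshold splits the trace; sub-
  threshold runs shorter than 0.8 s are absorbed into the surrounding
  movement (they are not rest), and the resulting movement periods are
  flagged excluded when shorter than 0.5 s or slower than 0.5 cm/s on
  average. A movement onset is the threshold crossing ending a rest period
  and the offset the crossing followed by a rest period.
* open-field ambulation: runs of velocity > 2 cm/s, merged across gaps not
  longer than 0.5 s, kept when longer than 0.5 s.
* open-field immobility: runs of activity change < 2% per frame with the
  same merge/duration rules. The activity series is abstract (percent
  pixel change per frame); when only velocity exists a declared velocity
  proxy may be thresholded instead, flagged in the output metadata.

Sample conventions: a sample belongs to the above-threshold side only when
strictly beyond the threshold (equality falls below); intervals are
half-open ``[onset, offset)`` and durations are counted in samples over the
sampling rate, so boundaries are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .config import BoutConfig
from .errors import ParameterError
from .io import VelocityTrace


@dataclass
class Bout:
    """A contiguous behavioral epoch."""

    onset_s: float
    offset_s: float
    kind: str  # movement | rest | ambulation | immobility
    mean_velocity: float = np.nan
    excluded: bool = False

    @property
    def duration_s(self) -> float:
        return self.offset_s - self.onset_s


@dataclass
class BoutSet:
    """Ordered, non-overlapping (within kind) bouts plus session context."""

    bouts: list
    session_duration_s: float
    t0: float = 0.0
    meta: dict = field(default_factory=dict)

    def of_kind(self, kind: str, include_excluded: bool = False) -> list:
        return [b for b in self.bouts
                if b.kind == kind and (include_excluded or not b.excluded)]

    def onsets(self, kind: str = "movement") -> np.ndarray:
        return np.array([b.onset_s for b in self.of_kind(kind)])

    def offsets(self, kind: str = "movement") -> np.ndarray:
        return np.array([b.offset_s for b in self.of_kind(kind)])


def _runs(mask: np.ndarray) -> list:
    """Maximal runs of True as half-open index pairs ``(start, end)``."""
    if mask.size == 0:
        return []
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return list(zip(starts.tolist(), ends.tolist()))


def segment_treadmill(velocity: VelocityTrace,
                      params: Optional[BoutConfig] = None) -> BoutSet:
    """Segment a treadmill velocity trace into movement and rest bouts.

    Movement periods failing the duration (0.5 s) or mean-velocity
    (0.5 cm/s) rule are returned flagged ``excluded`` rather than dropped,
    so movement, rest and excluded periods partition the session. Sub-
    threshold runs touching the session edges count as rest regardless of
    length (the session boundary acts as a rest boundary).
    """
    p = params or BoutConfig()
    p.validate()
    velocity.validate()
    fs = velocity.sampling_rate
    t0 = float(velocity.time[0])
    n = velocity.velocity.size
    v = np.abs(velocity.velocity) if p.use_absolute_velocity else velocity.velocity
    above = v > p.treadmill_threshold_cm_s

    bouts: list[Bout] = []
    if n == 0:
        return BoutSet(bouts=[], session_duration_s=0.0, t0=t0)

    # rest = sub-threshold runs lasting >= min_rest, or touching an edge
    rest_runs = []
    for s, e in _runs(~above):
        dur = (e - s) / fs
        if dur >= p.treadmill_min_rest_s or s == 0 or e == n:
            rest_runs.append((s, e))

    # movement candidates: the complement of rest (short dips absorbed)
    move_runs = []
    pos = 0
    for s, e in rest_runs:
        if s > pos:
            move_runs.append((pos, s))
        pos = e
    if pos < n:
        move_runs.append((pos, n))

    for s, e in move_runs:
        dur = (e - s) / fs
        mean_v = float(np.mean(v[s:e]))
        excluded = (dur < p.treadmill_min_move_s
                    or mean_v < p.treadmill_min_move_mean_cm_s)
        bouts.append(Bout(onset_s=t0 + s / fs, offset_s=t0 + e / fs,
                          kind="movement", mean_velocity=mean_v, excluded=excluded))
    for s, e in rest_runs:
        bouts.append(Bout(onset_s=t0 + s / fs, offset_s=t0 + e / fs, kind="rest",
                          mean_velocity=float(np.mean(v[s:e]))))
    bouts.sort(key=lambda b: (b.onset_s, b.kind))
    return BoutSet(bouts=bouts, session_duration_s=n / fs, t0=t0,
                   meta={"mode": "treadmill",
                         "signed_velocity": not p.use_absolute_velocity})


def _merge_and_filter(runs: list, n: int, fs: float, t0: float, values: np.ndarray,
                      min_separation_s: float, min_duration_s: float,
                      kind: str) -> list:
    """Merge runs separated by gaps <= min_separation, keep runs > min_duration."""
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and (s - merged[-1][1]) / fs <= min_separation_s:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    bouts = []
    for s, e in merged:
        if (e - s) / fs > min_duration_s:
            bouts.append(Bout(onset_s=t0 + s / fs, offset_s=t0 + e / fs, kind=kind,
                              mean_velocity=float(np.mean(values[s:e]))))
    return bouts


def segment_openfield_ambulation(velocity: VelocityTrace,
                                 params: Optional[BoutConfig] = None) -> BoutSet:
    """Ambulation bouts: velocity > 2 cm/s, > 0.5 s long, separated by > 0.5 s.

    Gaps not longer than the minimum separation merge adjacent supra-
    threshold runs; merged runs failing the minimum duration are dropped.
    """
    p = params or BoutConfig()
    p.validate()
    velocity.validate()
    fs = velocity.sampling_rate
    v = np.abs(velocity.velocity) if p.use_absolute_velocity else velocity.velocity
    runs = _runs(v > p.ambulation_threshold_cm_s)
    bouts = _merge_and_filter(runs, v.size, fs, float(velocity.time[0]), v,
                              p.ambulation_min_separation_s, p.ambulation_min_s,
                              "ambulation")
    return BoutSet(bouts=bouts, session_duration_s=v.size / fs,
                   t0=float(velocity.time[0]), meta={"mode": "openfield_ambulation"})


def segment_immobility(activity: np.ndarray, sampling_rate: float,
                       params: Optional[BoutConfig] = None, t0: float = 0.0,
                       is_velocity_proxy: bool = False) -> BoutSet:
    """Immobility bouts: activity < 2% change, > 0.5 s long, separated by > 0.5 s.

    ``activity`` is percent pixel change per frame (typically 15 Hz video).
    When a velocity trace stands in for the activity series, pass
    ``is_velocity_proxy=True`` so the substitution is recorded in the
    output metadata.
    """
    p = params or BoutConfig()
    p.validate()
    activity = np.asarray(activity, dtype=float)
    if not np.all(np.isfinite(activity)):
        raise ParameterError("activity series must be finite")
    runs = _runs(activity < p.immobility_activity_threshold_pct)
    bouts = _merge_and_filter(runs, activity.size, sampling_rate, t0, activity,
                              p.immobility_min_separation_s, p.immobility_min_s,
                              "immobility")
    return BoutSet(bouts=bouts, session_duration_s=activity.size / sampling_rate,
                   t0=t0, meta={"mode": "openfield_immobility",
                                "velocity_proxy": bool(is_velocity_proxy)})


def bout_summaries(bout_set: BoutSet, kind: str = "movement",
                   window: Optional[tuple] = None,
                   include_excluded: bool = False) -> dict:
    """Per-kind summary statistics, optionally restricted to a time window.

    Bouts are clipped at the window edges. Returns bout frequency
    (bouts/s), mean duration (s), mean of per-bout mean velocities (cm/s)
    and percent of window time spent in the kind. With zero bouts the
    means are NaN and frequency/percent are 0.
    """
    if window is None:
        w0, w1 = bout_set.t0, bout_set.t0 + bout_set.session_duration_s
    else:
        w0, w1 = window
    if not w1 > w0:
        raise ParameterError("summary window must have positive length")
    length = w1 - w0
    clipped = []
    for b in bout_set.of_kind(kind, include_excluded=include_excluded):
        on, off = max(b.onset_s, w0), min(b.offset_s, w1)
        if off > on:
            clipped.append((on, off, b.mean_velocity))
    durations = np.array([off - on for on, off, _ in clipped])
    velocities = np.array([mv for _, _, mv in clipped])
    n = len(clipped)
    return {
        "kind": kind,
        "n_bouts": n,
        "frequency_hz": n / length,
        "mean_duration_s": float(np.mean(durations)) if n else float("nan"),
        "mean_velocity_cm_s": float(np.mean(velocities)) if n else float("nan"),
        "percent_time": float(durations.sum() / length * 100.0),
        "window_s": (float(w0), float(w1)),
    }
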