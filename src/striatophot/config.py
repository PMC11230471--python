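"""Pipeline configuration.

All tunable parameters of the analysis chain live in one nested dataclass,
:class:`PipelineConfig`, whose defaults are the values used throughout the
analyses this package implements: a 5 s sliding 10th-percentile baseline,
a second-order 3 Hz Butterworth reference filter, RANSAC affine referencing,
the 1.5% / 0.6 quality-control gate, the 0.25 cm/s treadmill and 2 cm/s
open-field bout thresholds, and the stimulation analysis windows.

The configuration serializes to YAML and round-trips byte-identically
(``to_yaml(from_yaml(text)) == text`` for text written by ``to_yaml``).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field, fields
from typing import Any

import yaml

from .errors import ParameterError


def _check(cond: bool, msg: str) -> None:
    if not cond:
        raise ParameterError(msg)


@dataclass
class BaselineConfig:
    """Sliding-percentile baseline (F0) settings.

    ``window_s`` is the full width of the centered window in seconds and
    ``percentile`` the rank used within each window. Windows shrink at the
    session edges instead of padding.
    """

    window_s: float = 5.0
    percentile: float = 10.0

    def validate(self) -> None:
        _check(self.window_s > 0, "baseline.window_s must be > 0")
        _check(0 < self.percentile < 100, "baseline.percentile must be in (0, 100)")


@dataclass
class ReferenceFilterConfig:
    """Low-pass filter applied to the pre-normalized isosbestic reference."""

    corner_hz: float = 3.0
    order: int = 2

    def validate(self) -> None:
        _check(self.corner_hz > 0, "filter.corner_hz must be > 0")
        _check(self.order >= 1, "filter.order must be >= 1")


@dataclass
class RansacConfig:
    """Robust affine referencing settings.

    ``residual_threshold_mads`` scales the inlier threshold in units of the
    median absolute deviation of ordinary-least-squares residuals.
    ``min_samples`` is the size of each RANSAC hypothesis subset: a float
    in (0, 1] is a fraction of the data, an int >= 2 an absolute count.
    Large subsets (default: half the samples) make every candidate model
    an OLS-stable fit, so the consensus slope is unbiased while gross
    outliers are still rejected; minimal 2-point subsets are available but
    give unstable slopes when inliers dominate.
    """

    min_samples: float = 0.5
    max_trials: int = 50
    residual_threshold_mads: float = 3.0
    seed: int = 0

    def validate(self) -> None:
        ok = (0 < self.min_samples <= 1) or (
            self.min_samples >= 2 and float(self.min_samples).is_integer())
        _check(ok, "ransac.min_samples must be a fraction in (0, 1] or an int >= 2")
        _check(self.max_trials >= 1, "ransac.max_trials must be >= 1")
        _check(self.residual_threshold_mads > 0,
               "ransac.residual_threshold_mads must be > 0")


@dataclass
class QCConfig:
    """Session inclusion gate.

    A session is kept only when the maximum ΔF/F expressed in percent
    exceeds ``min_max_dff_percent`` and the Pearson correlation between the
    final ΔF/F and the transformed UV reference stays below
    ``max_reference_correlation``.
    """

    min_max_dff_percent: float = 1.5
    max_reference_correlation: float = 0.6

    def validate(self) -> None:
        _check(self.min_max_dff_percent >= 0, "qc.min_max_dff_percent must be >= 0")
        _check(-1 <= self.max_reference_correlation <= 1,
               "qc.max_reference_correlation must be in [-1, 1]")


@dataclass
class BoutConfig:
    """Thresholds and duration rules for bout segmentation.

    Treadmill: movement/rest split at 0.25 cm/s; sub-threshold runs shorter
    than ``treadmill_min_rest_s`` are absorbed into movement; movement
    periods shorter than ``treadmill_min_move_s`` or slower on average than
    ``treadmill_min_move_mean_cm_s`` are flagged excluded.

    Open field: ambulation is velocity > 2 cm/s, immobility is activity
    change < 2% per frame; both require bouts longer than 0.5 s separated by
    more than 0.5 s.
    """

    treadmill_threshold_cm_s: float = 0.25
    treadmill_min_move_s: float = 0.5
    treadmill_min_move_mean_cm_s: float = 0.5
    treadmill_min_rest_s: float = 0.8
    ambulation_threshold_cm_s: float = 2.0
    ambulation_min_s: float = 0.5
    ambulation_min_separation_s: float = 0.5
    immobility_activity_threshold_pct: float = 2.0
    immobility_min_s: float = 0.5
    immobility_min_separation_s: float = 0.5
    use_absolute_velocity: bool = True

    def validate(self) -> None:
        for name in ("treadmill_threshold_cm_s", "treadmill_min_move_s",
                     "treadmill_min_move_mean_cm_s", "treadmill_min_rest_s",
                     "ambulation_threshold_cm_s", "ambulation_min_s",
                     "ambulation_min_separation_s",
                     "immobility_activity_threshold_pct",
                     "immobility_min_s", "immobility_min_separation_s"):
            _check(getattr(self, name) > 0, f"bouts.{name} must be > 0")


@dataclass
class StimWindowConfig:
    """Analysis windows for stimulation-locked dopamine metrics (seconds).

    Baseline: mean ΔF/F over the 2 s preceding stimulus onset. Reduction:
    mean over the 0.2 s before stimulus offset. Peak: mean over
    0.35-0.45 s after onset. Post-stimulus: mean over 3-8 s after offset.
    All windows are half-open ``[a, b)`` and each amplitude is reported
    relative to the trial baseline.
    """

    baseline_pre_s: float = 2.0
    reduction_pre_s: float = 0.2
    peak_window_s: tuple = (0.35, 0.45)
    post_window_s: tuple = (3.0, 8.0)

    def validate(self) -> None:
        _check(self.baseline_pre_s > 0, "stim.baseline_pre_s must be > 0")
        _check(self.reduction_pre_s > 0, "stim.reduction_pre_s must be > 0")
        _check(self.peak_window_s[0] < self.peak_window_s[1],
               "stim.peak_window_s must be increasing")
        _check(self.post_window_s[0] < self.post_window_s[1],
               "stim.post_window_s must be increasing")


@dataclass
class PerieventConfig:
    """Peri-event alignment and timing/slope statistics settings.

    ``rel_fs_hz`` is the sampling rate of the peri-event grid; normalized
    traces are decimated (anti-aliased) to this rate before alignment.
    ``max_search_s`` is the closed window used for the time of maximum
    activity and ``slope_window_s`` the half-open window of the pre-offset
    linear regression. ``literal_amplitude_sign`` flips stimulation
    amplitudes to baseline-minus-window.
    """

    rel_fs_hz: float = 100.0
    locomotion_window_s: tuple = (-2.0, 2.0)
    max_search_s: tuple = (-1.0, 1.0)
    slope_window_s: tuple = (-0.5, 0.5)
    literal_amplitude_sign: bool = False

    def validate(self) -> None:
        _check(self.rel_fs_hz > 0, "perievent.rel_fs_hz must be > 0")
        for name in ("locomotion_window_s", "max_search_s", "slope_window_s"):
            a, b = getattr(self, name)
            _check(a < b, f"perievent.{name} must be increasing")


@dataclass
class PipelineConfig:
    """Complete pipeline configuration with the default analysis values."""

    baseline: BaselineConfig = field(default_factory=BaselineConfig)
    reference_filter: ReferenceFilterConfig = field(default_factory=ReferenceFilterConfig)
    ransac: RansacConfig = field(default_factory=RansacConfig)
    # dopamine chain: stimulation epochs are structural outliers with large
    # offsets, so the fit must hypothesize from minimal samples and keep a
    # tight inlier band to land on the unstimulated baseline relation
    ransac_rdam: RansacConfig = field(default_factory=lambda: RansacConfig(
        min_samples=2, max_trials=100, residual_threshold_mads=1.0))
    qc: QCConfig = field(default_factory=QCConfig)
    bouts: BoutConfig = field(default_factory=BoutConfig)
    stim_windows: StimWindowConfig = field(default_factory=StimWindowConfig)
    perievent: PerieventConfig = field(default_factory=PerieventConfig)
    # numeric guard for divisions, relative to the session median of the divisor
    epsilon_rel: float = 1e-9
    # rotary encoder calibration: 10 cm/s at 2.5 V
    encoder_cm_s_per_volt: float = 4.0
    seed: int = 0

    def validate(self) -> None:
        for f in fields(self):
            v = getattr(self, f.name)
            if dataclasses.is_dataclass(v):
                v.validate()
        _check(self.epsilon_rel > 0, "epsilon_rel must be > 0")
        _check(self.encoder_cm_s_per_volt > 0, "encoder_cm_s_per_volt must be > 0")

    # -- serialization --------------------------------------------------

    def to_dict(self) -> dict:
        return _as_plain_dict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        return _from_plain_dict(cls, d)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True, default_flow_style=False)

    @classmethod
    def from_yaml(cls, text: str) -> "PipelineConfig":
        data = yaml.safe_load(text)
        if not isinstance(data, dict):
            raise ParameterError("config YAML must map keys to values")
        return cls.from_dict(data)

    def save(self, path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(self.to_yaml())

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        with open(path, "r", encoding="utf-8") as fh:
            return cls.from_yaml(fh.read())


def _as_plain_dict(obj: Any) -> Any:
    if dataclasses.is_dataclass(obj):
        return {f.name: _as_plain_dict(getattr(obj, f.name)) for f in fields(obj)}
    if isinstance(obj, tuple):
        return [_as_plain_dict(v) for v in obj]
    return obj


def _from_plain_dict(cls, d: dict):
    kwargs = {}
    for f in fields(cls):
        if f.name not in d:
            continue
        v = d[f.name]
        sub_default = (f.default_factory() if f.default_factory is not dataclasses.MISSING
                       else f.default)
        if dataclasses.is_dataclass(sub_default):
            kwargs[f.name] = _from_plain_dict(type(sub_default), v)
        else:
            if isinstance(sub_default, tuple) and isinstance(v, list):
                v = tuple(v)
            kwargs[f.name] = v
    unknown = set(d) - {f.name for f in fields(cls)}
    if unknown:
        raise ParameterError(f"unknown config keys: {sorted(unknown)}")
    return cls(**kwargs)
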