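"""Fluorescence normalization: ΔF/F chains, referencing and QC.

Two normalization chains are implemented, one per sensor:

GCaMP chain (calcium, locomotion analyses)
    1. F0 per channel: 10th percentile over a 5 s sliding window.
    2. Pre-normalize both channels: ΔF/F0 = (F − F0) / F0.
    3. Low-pass the pre-normalized UV reference (2nd-order Butterworth,
       3 Hz corner, zero-phase).
    4. RANSAC ordinary-least-squares affine fit of the filtered reference
       onto the pre-normalized signal, absorbing gain/offset differences.
    5. Final ΔF/F = pre-normalized signal − transformed reference; the
       transformed reference is reported as "UV ΔF/F".
    6. QC gate: keep only sessions with max ΔF/F > 1.5% and
       corr(ΔF/F, UV ΔF/F) < 0.6.
    7. z-score with the mean and SD of the entire session.

rDA3m chain (dopamine, optogenetic stimulation)
    A RANSAC affine fit maps the raw demodulated UV reference onto the raw
    demodulated rDA3m trace; the fitted trace is the reference level F,
    ΔF = signal − F and ΔF/F = ΔF / F. No percentile baseline and no
    pre-normalization: the fit is deliberately run on raw channels so the
    large sustained offsets produced by stimulation survive as ΔF/F
    excursions rather than being absorbed into a baseline.

The same multiplicative bleaching and additive, affinely shared motion
artifacts that these chains assume are what the synthetic generator
produces, which is how the referencing step is validated end to end.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import signal as sps
from sklearn.linear_model import LinearRegression, RANSACRegressor

from ._percentile import sliding_percentile
from .config import PipelineConfig
from .errors import DataError, FitError, NumericGuardError, ParameterError
from .io import PhotometrySession


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclass
class RansacFit:
    """Affine map reference → signal fitted by RANSAC."""

    slope: float
    intercept: float
    inlier_mask: np.ndarray
    n_iterations: int
    residual_threshold: float
    min_samples: int
    seed: int
    degenerate: bool = False

    def transform(self, reference: np.ndarray) -> np.ndarray:
        return self.slope * np.asarray(reference, dtype=float) + self.intercept


@dataclass
class QCResult:
    """Session inclusion verdict.

    ``max_dff_percent`` is the session maximum of ΔF/F in percent;
    ``signal_reference_correlation`` the Pearson r between the final ΔF/F
    and the transformed UV reference. A session passes when the maximum
    exceeds ``threshold_max`` and the correlation stays below
    ``threshold_corr``.
    """

    max_dff_percent: float
    signal_reference_correlation: float
    passed: bool
    threshold_max: float = 1.5
    threshold_corr: float = 0.6


@dataclass
class NormalizedTrace:
    """Final ΔF/F with all intermediates of the normalization chain."""

    time: np.ndarray
    dff: np.ndarray
    zscore: np.ndarray
    transformed_reference: np.ndarray
    qc: QCResult
    chain: str
    sampling_rate: float
    fit: Optional[RansacFit] = None
    f0_signal: Optional[np.ndarray] = None
    f0_reference: Optional[np.ndarray] = None
    prenorm_signal: Optional[np.ndarray] = None
    prenorm_reference: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# Elementary operations
# ---------------------------------------------------------------------------

def sliding_percentile_baseline(trace: np.ndarray, window_s: float = 5.0,
                                percentile: float = 10.0,
                                sampling_rate: float = 1000.0) -> np.ndarray:
    """Sliding-percentile baseline F0.

    ``out[i]`` is the ``percentile`` of the trace over the centered window
    of width ``window_s`` clipped to the trace bounds (shrinking windows at
    the edges, no padding). Percentiles use linear interpolation between
    order statistics.
    """
    if window_s <= 0 or not (0 < percentile < 100):
        raise ParameterError("window_s must be > 0 and percentile in (0, 100)")
    trace = np.asarray(trace, dtype=float)
    if not np.all(np.isfinite(trace)):
        raise DataError("trace must be finite")
    half_width = int(round(window_s * sampling_rate / 2.0))
    if 2 * half_width + 1 < 2:
        raise ParameterError(
            f"window of {window_s} s at {sampling_rate} Hz spans < 2 samples")
    return sliding_percentile(trace, half_width, percentile)


def prenormalize(trace: np.ndarray, baseline: np.ndarray,
                 epsilon_rel: float = 1e-9) -> np.ndarray:
    """Per-channel ΔF/F0 = (trace − baseline) / baseline.

    The baseline must stay above ``epsilon_rel`` times its session median
    wherever it is used as a divisor.
    """
    trace = np.asarray(trace, dtype=float)
    baseline = np.asarray(baseline, dtype=float)
    if trace.shape != baseline.shape:
        raise DataError("trace and baseline must have equal length")
    eps = epsilon_rel * abs(float(np.median(baseline)))
    bad = baseline <= eps
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise NumericGuardError(
            f"baseline <= epsilon ({eps:.3g}) first at sample {idx}")
    return (trace - baseline) / baseline


def lowpass_reference(prenorm_reference: np.ndarray, corner_hz: float = 3.0,
                      order: int = 2, sampling_rate: float = 1000.0) -> np.ndarray:
    """Zero-phase Butterworth low-pass (forward-backward, DC gain 1).

    Applied to the pre-normalized UV reference before the affine fit.
    Forward-backward filtering squares the magnitude response, so a pure
    tone at frequency f is attenuated by |H(f)|^2.
    """
    nyquist = sampling_rate / 2.0
    if not (0 < corner_hz < nyquist):
        raise ParameterError(
            f"corner frequency {corner_hz} Hz must lie in (0, {nyquist}) Hz")
    sos = sps.butter(order, corner_hz, btype="low", fs=sampling_rate, output="sos")
    return sps.sosfiltfilt(sos, np.asarray(prenorm_reference, dtype=float))


def fit_reference(reference: np.ndarray, signal: np.ndarray,
                  min_samples: float = 0.5, max_trials: int = 50,
                  residual_threshold_mads: float = 3.0, seed: int = 0) -> RansacFit:
    """Robust affine fit ``signal ≈ slope·reference + intercept`` via RANSAC.

    The inlier residual threshold is ``residual_threshold_mads`` times the
    median absolute deviation of ordinary-least-squares residuals; each
    hypothesis is fit on a random subset of ``min_samples`` samples (a
    fraction when < 1). If the OLS residuals are (numerically) all zero
    the relation is exactly affine and the OLS fit is returned directly
    with every sample an inlier. The final slope/intercept always equal an
    OLS refit on the inlier set.
    """
    reference = np.asarray(reference, dtype=float)
    signal = np.asarray(signal, dtype=float)
    if reference.shape != signal.shape:
        raise DataError("reference and signal must have equal length")
    min_abs = min_samples if min_samples >= 2 else 2
    if reference.size < max(min_abs, 2):
        raise DataError("too few samples for an affine fit")
    if float(np.ptp(reference)) == 0.0:
        raise FitError("reference has zero variance; affine fit is degenerate")

    X = reference.reshape(-1, 1)
    ols = LinearRegression().fit(X, signal)
    resid = signal - ols.predict(X)
    mad = float(np.median(np.abs(resid - np.median(resid))))
    scale = max(1.0, float(np.max(np.abs(signal))))
    if mad <= 1e-12 * scale:
        # exactly (or numerically) affine: OLS is already the robust answer
        return RansacFit(slope=float(ols.coef_[0]), intercept=float(ols.intercept_),
                         inlier_mask=np.ones(reference.size, dtype=bool),
                         n_iterations=0, residual_threshold=0.0,
                         min_samples=min_samples, seed=seed)

    threshold = residual_threshold_mads * mad
    ms = float(min_samples) if 0 < min_samples < 1 else int(min_samples)
    ransac = RANSACRegressor(estimator=LinearRegression(),
                             min_samples=ms,
                             residual_threshold=threshold,
                             max_trials=max_trials,
                             random_state=seed)
    ransac.fit(X, signal)
    est = ransac.estimator_
    return RansacFit(slope=float(est.coef_[0]), intercept=float(est.intercept_),
                     inlier_mask=np.asarray(ransac.inlier_mask_, dtype=bool),
                     n_iterations=int(ransac.n_trials_),
                     residual_threshold=float(threshold),
                     min_samples=min_samples, seed=seed)


def reference_subtract(prenorm_signal: np.ndarray, fit: RansacFit,
                       filtered_reference: np.ndarray):
    """Final ΔF/F = pre-normalized signal − affinely transformed reference.

    Returns ``(dff, transformed_reference)``; the transformed reference is
    the "UV ΔF/F" trace.
    """
    prenorm_signal = np.asarray(prenorm_signal, dtype=float)
    filtered_reference = np.asarray(filtered_reference, dtype=float)
    if prenorm_signal.shape != filtered_reference.shape:
        raise DataError("signal and reference must have equal length")
    transformed = fit.transform(filtered_reference)
    return prenorm_signal - transformed, transformed


def qc_gate(dff: np.ndarray, transformed_reference: np.ndarray,
            threshold_max: float = 1.5, threshold_corr: float = 0.6) -> QCResult:
    """Apply the session inclusion rule.

    Pass requires max ΔF/F (in percent) above ``threshold_max`` and Pearson
    correlation between ΔF/F and the transformed UV reference below
    ``threshold_corr``. A constant trace on either side yields correlation 0
    (flagged degenerate by construction, not an error).
    """
    dff = np.asarray(dff, dtype=float)
    if not np.all(np.isfinite(dff)):
        raise DataError("dff must be finite")
    max_pct = 100.0 * float(np.max(dff))
    ref = np.asarray(transformed_reference, dtype=float)
    if float(np.std(dff)) == 0.0 or float(np.std(ref)) == 0.0:
        corr = 0.0
    else:
        corr = float(np.corrcoef(dff, ref)[0, 1])
    passed = (max_pct > threshold_max) and (corr < threshold_corr)
    return QCResult(max_dff_percent=max_pct, signal_reference_correlation=corr,
                    passed=passed, threshold_max=threshold_max,
                    threshold_corr=threshold_corr)


def zscore_session(dff: np.ndarray) -> np.ndarray:
    """z-score with the mean and SD of the entire recording session.

    A zero-variance trace maps to zeros.
    """
    dff = np.asarray(dff, dtype=float)
    sd = float(np.std(dff))
    if sd == 0.0:
        return np.zeros_like(dff)
    return (dff - float(np.mean(dff))) / sd


# ---------------------------------------------------------------------------
# Full chains
# ---------------------------------------------------------------------------

def normalize_gcamp(session: PhotometrySession,
                    config: Optional[PipelineConfig] = None) -> NormalizedTrace:
    """Run the full GCaMP normalization chain on a session.

    See the module docstring for the step order. If the filtered reference
    is constant (e.g. a noiseless null session) the affine fit is
    degenerate; the transform is then the zero map, so the final ΔF/F
    equals the pre-normalized signal.
    """
    if session.sensor_kind != "gcamp":
        raise ParameterError(
            f"normalize_gcamp requires sensor_kind 'gcamp', got '{session.sensor_kind}'")
    cfg = config or PipelineConfig()
    fs = session.sampling_rate

    f0_sig = sliding_percentile_baseline(session.signal, cfg.baseline.window_s,
                                         cfg.baseline.percentile, fs)
    f0_ref = sliding_percentile_baseline(session.reference, cfg.baseline.window_s,
                                         cfg.baseline.percentile, fs)
    pre_sig = prenormalize(session.signal, f0_sig, cfg.epsilon_rel)
    pre_ref = prenormalize(session.reference, f0_ref, cfg.epsilon_rel)
    filt_ref = lowpass_reference(pre_ref, cfg.reference_filter.corner_hz,
                                 cfg.reference_filter.order, fs)

    if float(np.ptp(filt_ref)) <= 1e-12 * max(1.0, float(np.max(np.abs(filt_ref)))):
        fit = RansacFit(slope=0.0, intercept=0.0,
                        inlier_mask=np.ones(filt_ref.size, dtype=bool),
                        n_iterations=0, residual_threshold=0.0,
                        min_samples=cfg.ransac.min_samples, seed=cfg.ransac.seed,
                        degenerate=True)
    else:
        fit = fit_reference(filt_ref, pre_sig,
                            min_samples=cfg.ransac.min_samples,
                            max_trials=cfg.ransac.max_trials,
                            residual_threshold_mads=cfg.ransac.residual_threshold_mads,
                            seed=cfg.ransac.seed)
    dff, transformed = reference_subtract(pre_sig, fit, filt_ref)
    qc = qc_gate(dff, transformed, cfg.qc.min_max_dff_percent,
                 cfg.qc.max_reference_correlation)
    return NormalizedTrace(time=session.time, dff=dff, zscore=zscore_session(dff),
                           transformed_reference=transformed, qc=qc, chain="gcamp",
                           sampling_rate=fs, fit=fit, f0_signal=f0_sig,
                           f0_reference=f0_ref, prenorm_signal=pre_sig,
                           prenorm_reference=pre_ref, meta=dict(session.meta))


def normalize_rdam(session: PhotometrySession,
                   config: Optional[PipelineConfig] = None) -> NormalizedTrace:
    """Run the dopamine-sensor chain: referenced F, then ΔF/F = (F_raw − F)/F.

    The RANSAC affine fit runs on the raw demodulated channels so sustained
    stimulation-driven offsets are preserved in ΔF/F. Samples where the
    fitted F falls below the numeric guard raise
    :class:`~striatophot.errors.NumericGuardError`.
    """
    if session.sensor_kind != "rdam":
        raise ParameterError(
            f"normalize_rdam requires sensor_kind 'rdam', got '{session.sensor_kind}'")
    cfg = config or PipelineConfig()

    fit = fit_reference(session.reference, session.signal,
                        min_samples=cfg.ransac_rdam.min_samples,
                        max_trials=cfg.ransac_rdam.max_trials,
                        residual_threshold_mads=cfg.ransac_rdam.residual_threshold_mads,
                        seed=cfg.ransac_rdam.seed)
    f_trace = fit.transform(session.reference)
    eps = cfg.epsilon_rel * abs(float(np.median(f_trace)))
    bad = f_trace <= eps
    if bad.any():
        idx = int(np.flatnonzero(bad)[0])
        raise NumericGuardError(
            f"referenced F <= epsilon ({eps:.3g}) first at sample {idx}")
    dff = (session.signal - f_trace) / f_trace
    qc = qc_gate(dff, f_trace, cfg.qc.min_max_dff_percent,
                 cfg.qc.max_reference_correlation)
    return NormalizedTrace(time=session.time, dff=dff, zscore=zscore_session(dff),
                           transformed_reference=f_trace, qc=qc, chain="rdam",
                           sampling_rate=session.sampling_rate, fit=fit,
                           meta=dict(session.meta))


def decimate_trace(trace: np.ndarray, sampling_rate: float,
                   target_fs: float) -> tuple[np.ndarray, float]:
    """Anti-aliased decimation to (approximately) ``target_fs``.

    Returns the decimated trace and its actual sampling rate. Used before
    peri-event alignment; 1 kHz carries no information for ~1 s indicator
    kernels and coarser grids keep peri-event matrices small.
    """
    factor = int(round(sampling_rate / target_fs))
    if factor <= 1:
        return np.asarray(trace, dtype=float), sampling_rate
    out = sps.decimate(np.asarray(trace, dtype=float), factor, ftype="fir",
                       zero_phase=True)
    return out, sampling_rate / factor
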