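"""Synthetic session generator with recorded ground truth.

The generator produces velocity traces and two-channel photometry sessions
with the statistical structure the normalization and peri-event analyses
assume, so the whole chain can be validated without animal recordings:

* slow photobleaching, multiplicative and channel-specific (double
  exponential decay with different kinetics per channel);
* motion artifacts, additive and affinely shared: the same smoothed
  positive bump waveform enters both channels with channel-specific gain
  and offset, scaled by each channel's bleach factor (motion modulates the
  collected light multiplicatively) — so at every instant the two channels
  see the artifact through an affine map, the model the RANSAC referencing
  assumes;
* calcium transients (difference-of-exponentials kernel, ~1 s decay) at
  Poisson times whose rate switches with locomotion state;
* a deterministic activity ramp tied to each locomotion bout offset:
  ``patch_like`` activity ramps up over a lead window before the offset
  and peaks shortly after the animal stops; ``matrix_like`` activity
  declines over the lead window and reaches baseline at the offset;
* treadmill locomotion as alternating rest and movement epochs with
  trapezoidal velocity profiles (steep 10 ms edges, so the 0.25 cm/s
  threshold crossing stays within one sample of the scheduled boundary);
* dopamine-sensor sessions with stimulation trains (2/5/15 s trials,
  ~10 per duration, >= 45 s gaps) injecting a sustained suppression, an
  optional onset peak near +0.4 s and an optional post-offset rebound.

Every output carries a :class:`GroundTruth` and is bit-reproducible from
``(params, seed)``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.signal import fftconvolve

from .errors import ParameterError
from .io import EventTrain, PhotometrySession, VelocityTrace

__all__ = ["SimParams", "GroundTruth", "simulate_locomotion",
           "simulate_photometry", "simulate_stim_session"]


@dataclass
class SimParams:
    """Generator parameters (units in names; rates in Hz unless stated)."""

    duration_s: float = 60.0
    sampling_rate: float = 1000.0

    # photobleaching: multiplicative decay a1*exp(-t/tau1) + a2*exp(-t/tau2)
    bleach_signal: tuple = (0.10, 120.0, 0.90, 3600.0)
    bleach_reference: tuple = (0.15, 90.0, 0.85, 2600.0)
    baseline_signal: float = 100.0
    baseline_reference: float = 60.0

    # shared motion artifact: sparse positive coupling bumps (Poisson impulses
    # with half-normal amplitudes, Gaussian-smoothed), scaled per channel by
    # the bleach factor (motion modulates collected light multiplicatively)
    artifact_rate_per_min: float = 20.0
    artifact_amp_sd: float = 4.0
    artifact_width_s: float = 0.3
    artifact_gain_signal: float = 1.0
    artifact_gain_reference: float = 0.8
    artifact_offset_reference: float = 0.0

    # calcium transients (relative fluorescence units, i.e. ΔF/F-sized)
    transient_rise_s: float = 0.05
    transient_decay_s: float = 1.0
    transient_amp: float = 0.03
    transient_amp_jitter: float = 0.3
    rate_move_hz: float = 0.4
    rate_rest_hz: float = 0.05

    # locomotion-offset coupling
    coupling_profile: str = "none"  # none | patch_like | matrix_like
    coupling_amp: float = 0.05
    coupling_lead_s: float = 0.5
    coupling_peak_delay_s: float = 0.2
    coupling_decay_s: float = 0.3
    coupling_rise_s: float = 0.2
    coupling_base_frac: float = 0.4  # within-bout plateau, fraction of amp

    # measurement noise (arbitrary units, per channel)
    noise_sd_signal: float = 0.05
    noise_sd_reference: float = 0.03

    # locomotion epochs
    move_mean_s: float = 4.0
    rest_mean_s: float = 4.0
    min_epoch_s: float = 1.2
    move_speed_cm_s: float = 4.0
    speed_jitter: float = 0.25
    rest_noise_cm_s: float = 0.08  # kept well below the 0.25 cm/s threshold
    edge_ramp_s: float = 0.01
    schedule: Optional[list] = None  # fixed [(onset_s, offset_s), ...]

    # optogenetic stimulation protocol
    stim_durations_s: tuple = (2.0, 5.0, 15.0)
    trials_per_duration: int = 10
    inter_trial_gap_s: float = 45.0
    stim_lead_in_s: float = 20.0
    stim_tail_s: float = 20.0
    stim_frequency_label: str = "20Hz"

    # injected dopamine response (ΔF/F units)
    stim_depth: float = -0.2
    stim_tau_on_s: float = 0.5
    stim_tau_off_s: float = 0.8
    stim_peak_amp: float = 0.0
    stim_peak_time_s: float = 0.4
    stim_peak_width_s: float = 0.05
    stim_rebound_amp: float = 0.0
    stim_rebound_time_s: float = 5.0
    stim_rebound_width_s: float = 1.0
    # affine map reference -> dopamine baseline F
    rdam_gain: float = 1.6
    rdam_offset: float = 10.0

    def validate(self) -> None:
        if self.duration_s <= 0 or self.sampling_rate <= 0:
            raise ParameterError("duration_s and sampling_rate must be > 0")
        for name in ("artifact_rate_per_min", "artifact_amp_sd", "rate_move_hz",
                     "rate_rest_hz", "noise_sd_signal", "noise_sd_reference",
                     "rest_noise_cm_s"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0")
        for tau in (self.transient_rise_s, self.transient_decay_s,
                    *self.bleach_signal[1::2], *self.bleach_reference[1::2]):
            if not tau > 0:
                raise ParameterError("time constants must be > 0")
        if self.coupling_profile not in ("none", "patch_like", "matrix_like"):
            raise ParameterError(f"unknown coupling_profile '{self.coupling_profile}'")


@dataclass
class GroundTruth:
    """Generative parameters actually realized in one synthetic session."""

    rng_seed: int
    true_bouts: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))
    true_transient_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_artifact_trace: Optional[np.ndarray] = None
    true_bleach_params: dict = field(default_factory=dict)
    true_coupling_profile: str = "none"
    true_ramp_peak_times: np.ndarray = field(default_factory=lambda: np.empty(0))
    true_coupling_trace: Optional[np.ndarray] = None
    true_activity_trace: Optional[np.ndarray] = None
    true_stim: Optional[list] = None  # per-trial dicts
    true_response_trace: Optional[np.ndarray] = None


def _bleach(t: np.ndarray, params: tuple) -> np.ndarray:
    a1, tau1, a2, tau2 = params
    return a1 * np.exp(-t / tau1) + a2 * np.exp(-t / tau2)


def _seeded(seed: int, stream: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(seed), stream]))


# ---------------------------------------------------------------------------
# Locomotion
# ---------------------------------------------------------------------------

def simulate_locomotion(params: SimParams, seed: int = 0):
    """Generate a treadmill velocity trace of alternating rest and movement.

    With ``params.schedule`` set, movement bouts occur exactly at the given
    ``(onset_s, offset_s)`` intervals; otherwise epoch durations are drawn
    from shifted exponentials. Movement velocity follows a trapezoid with
    10 ms edges so the 0.25 cm/s crossing stays within one sample of the
    scheduled boundary; rest velocity is uniform noise well below the
    threshold. Returns ``(VelocityTrace, GroundTruth)``.
    """
    params.validate()
    if params.duration_s < 10:
        raise ParameterError("locomotion simulation needs duration_s >= 10")
    rng = _seeded(seed, 1)
    fs = params.sampling_rate
    n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs

    if params.schedule is not None:
        bouts = [(float(a), float(b)) for a, b in params.schedule]
    elif params.move_mean_s <= 0:
        bouts = []
    else:
        if params.move_mean_s + params.rest_mean_s > params.duration_s:
            raise ParameterError("mean epoch durations exceed the session duration")
        bouts = []
        pos = params.min_epoch_s + rng.exponential(
            max(params.rest_mean_s - params.min_epoch_s, 1e-6))
        while True:
            dur = params.min_epoch_s + rng.exponential(
                max(params.move_mean_s - params.min_epoch_s, 1e-6))
            if pos + dur > params.duration_s - params.min_epoch_s:
                break
            bouts.append((pos, pos + dur))
            pos += dur + params.min_epoch_s + rng.exponential(
                max(params.rest_mean_s - params.min_epoch_s, 1e-6))

    # snap bout boundaries to the sample grid: the ground truth records the
    # realized bouts, so boundary recovery is well-defined at 1-sample scale
    bouts = [(round(a * fs) / fs, round(b * fs) / fs) for a, b in bouts]
    bouts = [(a, b) for a, b in bouts if b > a]

    velocity = np.zeros(n)
    if params.rest_noise_cm_s > 0:
        velocity += rng.uniform(-params.rest_noise_cm_s, params.rest_noise_cm_s, n)
    ramp = max(params.edge_ramp_s, 1.0 / fs)
    for on, off in bouts:
        speed = params.move_speed_cm_s
        if params.speed_jitter > 0:
            speed *= math.exp(params.speed_jitter * rng.standard_normal()
                              - 0.5 * params.speed_jitter ** 2)
        i0, i1 = int(round(on * fs)), int(round(off * fs))
        seg_t = t[i0:i1]
        profile = np.minimum(1.0, np.minimum((seg_t - on) / ramp,
                                             (off - seg_t) / ramp))
        velocity[i0:i1] = speed * np.maximum(profile, 0.0)

    trace = VelocityTrace(time=t, velocity=velocity, sampling_rate=fs)
    truth = GroundTruth(rng_seed=int(seed),
                        true_bouts=np.array(bouts, dtype=float).reshape(-1, 2))
    return trace, truth


# ---------------------------------------------------------------------------
# Photometry (GCaMP chain)
# ---------------------------------------------------------------------------

def _transient_kernel(params: SimParams, fs: float) -> np.ndarray:
    tk = np.arange(0.0, 6.0 * params.transient_decay_s, 1.0 / fs)
    k = np.exp(-tk / params.transient_decay_s) - np.exp(-tk / params.transient_rise_s)
    peak = float(np.max(k))
    return k / peak if peak > 0 else k


def _coupling_trace(params: SimParams, t: np.ndarray, bouts: np.ndarray):
    """Deterministic bout-locked activity component and its per-bout peaks."""
    c = np.zeros_like(t)
    peaks = []
    amp, base = params.coupling_amp, params.coupling_amp * params.coupling_base_frac
    lead, rise = params.coupling_lead_s, params.coupling_rise_s
    for on, off in bouts:
        if params.coupling_profile == "patch_like":
            # plateau from onset, linear ramp through the offset, exp decay
            peak_t = off + params.coupling_peak_delay_s
            in_rise = (t >= on) & (t < on + rise)
            c[in_rise] = np.maximum(c[in_rise], base * (t[in_rise] - on) / rise)
            plateau = (t >= on + rise) & (t < off - lead)
            c[plateau] = np.maximum(c[plateau], base)
            ramping = (t >= off - lead) & (t < peak_t)
            frac = (t[ramping] - (off - lead)) / (lead + params.coupling_peak_delay_s)
            c[ramping] = np.maximum(c[ramping], base + (amp - base) * frac)
            after = t >= peak_t
            c[after] = np.maximum(
                c[after], amp * np.exp(-(t[after] - peak_t) / params.coupling_decay_s))
            peaks.append(peak_t)
        elif params.coupling_profile == "matrix_like":
            # plateau from onset, linear decline reaching zero at the offset
            in_rise = (t >= on) & (t < on + rise)
            c[in_rise] = np.maximum(c[in_rise], amp * (t[in_rise] - on) / rise)
            plateau = (t >= on + rise) & (t < off - lead)
            c[plateau] = np.maximum(c[plateau], amp)
            declining = (t >= off - lead) & (t < off)
            c[declining] = np.maximum(
                c[declining], amp * (off - t[declining]) / lead)
            peaks.append(off - lead)
    return c, np.asarray(peaks, dtype=float)


def simulate_photometry(params: SimParams, velocity: Optional[VelocityTrace] = None,
                        seed: int = 0, true_bouts: Optional[np.ndarray] = None):
    """Generate a two-channel GCaMP photometry session.

    ``signal = B_s · bleach_s(t) · (1 + activity) + g_s · artifact + noise``
    and ``reference = B_r · bleach_r(t) + g_r · artifact + offset + noise``,
    where ``activity`` sums Poisson-timed calcium transients (rate switched
    by locomotion state) and the bout-offset coupling component. Returns
    ``(PhotometrySession, GroundTruth)``.
    """
    params.validate()
    rng = _seeded(seed, 2)
    fs = params.sampling_rate
    if velocity is not None:
        if abs(velocity.sampling_rate - fs) > 1e-9:
            raise ParameterError("velocity and photometry sampling rates differ")
        n = velocity.velocity.size
    else:
        n = int(round(params.duration_s * fs))
    t = np.arange(n) / fs

    if true_bouts is None:
        if velocity is not None:
            from .behavior import _runs  # threshold-derive the movement state
            above = np.abs(velocity.velocity) > 0.25
            true_bouts = np.array([(s / fs, e / fs) for s, e in _runs(above)],
                                  dtype=float).reshape(-1, 2)
        else:
            true_bouts = np.empty((0, 2))
    moving = np.zeros(n, dtype=bool)
    for on, off in true_bouts:
        moving[int(round(on * fs)):int(round(off * fs))] = True

    # transients at state-dependent Poisson times
    rate = np.where(moving, params.rate_move_hz, params.rate_rest_hz)
    event_mask = rng.random(n) < rate / fs
    event_idx = np.flatnonzero(event_mask)
    amps = params.transient_amp * np.exp(
        params.transient_amp_jitter * rng.standard_normal(event_idx.size)
        - 0.5 * params.transient_amp_jitter ** 2)
    impulses = np.zeros(n)
    impulses[event_idx] = amps
    kernel = _transient_kernel(params, fs)
    transients = fftconvolve(impulses, kernel)[:n] if event_idx.size else np.zeros(n)

    coupling, ramp_peaks = _coupling_trace(params, t, true_bouts)
    activity = transients + coupling

    # shared artifact waveform: sparse positive bumps
    artifact = np.zeros(n)
    if params.artifact_rate_per_min > 0 and params.artifact_amp_sd > 0:
        a_mask = rng.random(n) < params.artifact_rate_per_min / 60.0 / fs
        a_idx = np.flatnonzero(a_mask)
        a_impulses = np.zeros(n)
        a_impulses[a_idx] = params.artifact_amp_sd * np.abs(
            rng.standard_normal(a_idx.size))
        gk_t = np.arange(-4 * params.artifact_width_s, 4 * params.artifact_width_s,
                         1.0 / fs)
        gk = np.exp(-0.5 * (gk_t / params.artifact_width_s) ** 2)
        artifact = fftconvolve(a_impulses, gk, mode="same")

    bleach_s = _bleach(t, params.bleach_signal)
    bleach_r = _bleach(t, params.bleach_reference)
    signal = bleach_s * (params.baseline_signal * (1.0 + activity)
                         + params.artifact_gain_signal * artifact)
    reference = (bleach_r * (params.baseline_reference
                             + params.artifact_gain_reference * artifact)
                 + params.artifact_offset_reference)
    if params.noise_sd_signal > 0:
        signal = signal + params.noise_sd_signal * rng.standard_normal(n)
    if params.noise_sd_reference > 0:
        reference = reference + params.noise_sd_reference * rng.standard_normal(n)

    events = []
    if len(true_bouts):
        events.append(EventTrain("locomotion", true_bouts[:, 0], true_bouts[:, 1]))
    session = PhotometrySession(
        time=t, signal=signal, reference=reference, sampling_rate=fs,
        sensor_kind="gcamp", events=events,
        meta={"synthetic": True, "rng_seed": int(seed),
              "coupling_profile": params.coupling_profile})
    truth = GroundTruth(
        rng_seed=int(seed), true_bouts=np.asarray(true_bouts, dtype=float),
        true_transient_times=event_idx / fs, true_artifact_trace=artifact,
        true_bleach_params={"signal": params.bleach_signal,
                            "reference": params.bleach_reference},
        true_coupling_profile=params.coupling_profile,
        true_ramp_peak_times=ramp_peaks, true_coupling_trace=coupling,
        true_activity_trace=activity)
    return session, truth


# ---------------------------------------------------------------------------
# Stimulation sessions (rDA3m chain)
# ---------------------------------------------------------------------------

def stim_response_trace(params: SimParams, t: np.ndarray,
                        trials: list) -> np.ndarray:
    """Evaluate the injected per-trial dopamine response in ΔF/F units.

    During stimulation the response approaches ``stim_depth`` exponentially
    (τ = ``stim_tau_on_s``); after the offset it relaxes back with
    ``stim_tau_off_s`` and an optional Gaussian rebound centered
    ``stim_rebound_time_s`` after the offset. An optional Gaussian onset
    peak sits ``stim_peak_time_s`` after the onset. This evaluator is also
    the ground-truth oracle used to verify metric recovery.
    """
    r = np.zeros_like(t)
    for trial in trials:
        on, off = trial["onset_s"], trial["offset_s"]
        depth, peak, reb = (trial["depth"], trial["peak_amp"], trial["rebound_amp"])
        during = (t >= on) & (t < off)
        r[during] += depth * (1.0 - np.exp(-(t[during] - on) / params.stim_tau_on_s))
        end_level = depth * (1.0 - math.exp(-(off - on) / params.stim_tau_on_s))
        after = t >= off
        r[after] += end_level * np.exp(-(t[after] - off) / params.stim_tau_off_s)
        if peak != 0.0:
            near = (t >= on) & (t < off + 2.0)
            r[near] += peak * np.exp(
                -0.5 * ((t[near] - on - params.stim_peak_time_s)
                        / params.stim_peak_width_s) ** 2)
        if reb != 0.0:
            w = (t >= off) & (t < off + params.stim_rebound_time_s
                              + 6 * params.stim_rebound_width_s)
            r[w] += reb * np.exp(
                -0.5 * ((t[w] - off - params.stim_rebound_time_s)
                        / params.stim_rebound_width_s) ** 2)
    return r


def simulate_stim_session(params: SimParams, seed: int = 0):
    """Generate an rDA3m session with an optogenetic stimulation train.

    Trials of each duration in ``stim_durations_s`` (default 2/5/15 s,
    10 trials each) are interleaved in a seeded random order with gaps of
    at least 45 s; the session length follows from the protocol. The
    signal is the affinely referenced baseline modulated by the injected
    response: ``signal = (gain·ref_clean + offset) · (1 + response) + noise``.
    Returns ``(PhotometrySession, GroundTruth)``.
    """
    params.validate()
    if params.inter_trial_gap_s < 45.0:
        raise ParameterError("stimulation trials must be separated by >= 45 s")
    rng = _seeded(seed, 3)
    fs = params.sampling_rate

    durations = [d for d in params.stim_durations_s
                 for _ in range(params.trials_per_duration)]
    order = rng.permutation(len(durations))
    trials = []
    pos = params.stim_lead_in_s
    for k in order:
        dur = durations[k]
        gap = params.inter_trial_gap_s + float(rng.uniform(0.0, 3.0))
        trials.append({
            "onset_s": pos, "offset_s": pos + dur, "duration_s": dur,
            "depth": params.stim_depth, "peak_amp": params.stim_peak_amp,
            "rebound_amp": params.stim_rebound_amp,
        })
        pos += dur + gap
    total_s = pos - params.inter_trial_gap_s + params.stim_tail_s
    n = int(round(total_s * fs))
    t = np.arange(n) / fs

    response = stim_response_trace(params, t, trials)
    bleach_r = _bleach(t, params.bleach_reference)
    ref_clean = params.baseline_reference * bleach_r
    f_true = params.rdam_gain * ref_clean + params.rdam_offset
    signal = f_true * (1.0 + response)
    reference = ref_clean.copy()
    if params.noise_sd_signal > 0:
        signal = signal + params.noise_sd_signal * rng.standard_normal(n)
    if params.noise_sd_reference > 0:
        reference = reference + params.noise_sd_reference * rng.standard_normal(n)

    onsets = np.array([tr["onset_s"] for tr in trials])
    offsets = np.array([tr["offset_s"] for tr in trials])
    session = PhotometrySession(
        time=t, signal=signal, reference=reference, sampling_rate=fs,
        sensor_kind="rdam",
        events=[EventTrain("stim", onsets, offsets)],
        meta={"synthetic": True, "rng_seed": int(seed),
              "stim_frequency": params.stim_frequency_label})
    for tr in trials:
        tr["depth_at_offset"] = tr["depth"] * (
            1.0 - math.exp(-tr["duration_s"] / params.stim_tau_on_s))
    truth = GroundTruth(rng_seed=int(seed), true_stim=trials,
                        true_response_trace=response,
                        true_bleach_params={"reference": params.bleach_reference})
    return session, truth
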