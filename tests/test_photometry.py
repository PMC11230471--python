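"""Normalization chain: baselines, filtering, referencing, QC, z-score."""

import numpy as np
import pytest

from striatophot import (DataError, FitError, NumericGuardError, ParameterError,
                         PhotometrySession, PipelineConfig, fit_reference,
                         lowpass_reference, normalize_gcamp, normalize_rdam,
                         prenormalize, qc_gate, reference_subtract,
                         sliding_percentile_baseline, zscore_session)
from striatophot.photometry import RansacFit
from striatophot.synthetic import SimParams, simulate_photometry


def brute_force_baseline(trace, window_s, percentile, fs):
    """Independent per-window oracle (naive percentile over explicit windows)."""
    hw = int(round(window_s * fs / 2.0))
    n = trace.size
    return np.array([np.percentile(trace[max(0, i - hw):min(n, i + hw + 1)],
                                   percentile) for i in range(n)])


class TestSlidingPercentile:
    def test_constant_trace(self):
        out = sliding_percentile_baseline(np.full(500, 7.0), 5.0, 10.0, 100.0)
        np.testing.assert_array_equal(out, 7.0)

    def test_window_spanning_whole_trace(self):
        # ascending 1..1000 with a 5 s window at 1 kHz: every clipped window
        # covers the full trace, so the baseline is its global 10th percentile
        trace = np.arange(1.0, 1001.0)
        out = sliding_percentile_baseline(trace, 5.0, 10.0, 1000.0)
        np.testing.assert_allclose(out, np.percentile(trace, 10.0), atol=1e-12)

    def test_step_trace_locality(self):
        fs = 100.0
        trace = np.concatenate([np.zeros(1000), np.full(1000, 10.0)])
        out = sliding_percentile_baseline(trace, 5.0, 10.0, fs)
        np.testing.assert_array_equal(out[:500], 0.0)
        np.testing.assert_array_equal(out[1500:], 10.0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_brute_force_random(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(50, 3000))
        fs = float(rng.choice([10.0, 50.0, 100.0]))
        q = float(rng.uniform(5, 95))
        trace = rng.normal(50, 10, n)
        out = sliding_percentile_baseline(trace, 5.0, q, fs)
        np.testing.assert_allclose(out, brute_force_baseline(trace, 5.0, q, fs),
                                   atol=1e-12, rtol=1e-12)

    def test_degenerate_window_rejected(self):
        with pytest.raises(ParameterError):
            sliding_percentile_baseline(np.ones(100), 0.001, 10.0, 100.0)
        with pytest.raises(ParameterError):
            sliding_percentile_baseline(np.ones(100), 5.0, 0.0, 100.0)


class TestPrenormalize:
    @pytest.mark.parametrize("trace,baseline,expected", [
        (12.0, 10.0, 0.2), (10.0, 10.0, 0.0), (9.0, 10.0, -0.1),
    ])
    def test_arithmetic(self, trace, baseline, expected):
        out = prenormalize(np.full(10, trace), np.full(10, baseline))
        np.testing.assert_allclose(out, expected, atol=1e-15)

    def test_guard_names_first_index(self):
        baseline = np.ones(10)
        baseline[4] = 0.0
        with pytest.raises(NumericGuardError, match="sample 4"):
            prenormalize(np.ones(10), baseline)


class TestLowpassReference:
    def test_dc_gain_unity(self):
        out = lowpass_reference(np.full(5000, 3.7), 3.0, 2, 1000.0)
        np.testing.assert_allclose(out, 3.7, atol=1e-9)

    @pytest.mark.parametrize("freq", [0.1, 1.0, 3.0, 10.0, 30.0])
    def test_tone_attenuation_closed_form(self, freq):
        # forward-backward second-order Butterworth: |H(f)|^2 = 1/(1+(f/fc)^4)
        fs, fc, dur = 1000.0, 3.0, 30.0
        t = np.arange(int(dur * fs)) / fs
        tone = np.sin(2 * np.pi * freq * t)
        out = lowpass_reference(tone, fc, 2, fs)
        mid = slice(int(5 * fs), int(25 * fs))
        gain = np.sqrt(np.mean(out[mid] ** 2) / np.mean(tone[mid] ** 2))
        expected = 1.0 / (1.0 + (freq / fc) ** 4)
        assert gain == pytest.approx(expected, rel=0.02)

    def test_corner_beyond_nyquist_rejected(self):
        with pytest.raises(ParameterError):
            lowpass_reference(np.ones(100), 60.0, 2, 100.0)


class TestFitReference:
    def test_exact_affine_recovered(self):
        rng = np.random.default_rng(0)
        ref = rng.normal(5, 1, 2000)
        fit = fit_reference(ref, 2.0 * ref + 1.0)
        assert fit.slope == pytest.approx(2.0, abs=1e-9)
        assert fit.intercept == pytest.approx(1.0, abs=1e-9)
        assert fit.inlier_mask.all()

    def test_gross_outliers_rejected(self):
        rng = np.random.default_rng(1)
        ref = rng.normal(5, 1, 4000)
        sig = 2.0 * ref + 1.0 + 0.01 * rng.standard_normal(4000)
        idx = rng.choice(4000, 200, replace=False)
        sig[idx] += rng.choice([-100.0, 100.0], 200)
        fit = fit_reference(ref, sig, seed=0)
        # oracle: OLS on the uncorrupted subset
        clean = np.setdiff1d(np.arange(4000), idx)
        slope_o, icpt_o = np.polyfit(ref[clean], sig[clean], 1)
        assert fit.slope == pytest.approx(slope_o, abs=1e-3)
        assert fit.intercept == pytest.approx(icpt_o, abs=1e-3)
        assert not fit.inlier_mask[idx].any()

    def test_inlier_refit_is_ols(self):
        rng = np.random.default_rng(2)
        ref = rng.normal(0, 1, 3000)
        sig = -0.5 * ref + 3.0 + 0.1 * rng.standard_normal(3000)
        fit = fit_reference(ref, sig, seed=1)
        m = fit.inlier_mask
        slope_o, icpt_o = np.polyfit(ref[m], sig[m], 1)
        assert fit.slope == pytest.approx(slope_o, abs=1e-9)
        assert fit.intercept == pytest.approx(icpt_o, abs=1e-9)

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(3)
        ref = rng.normal(0, 1, 1000)
        sig = ref + rng.standard_normal(1000)
        f1 = fit_reference(ref, sig, seed=42)
        f2 = fit_reference(ref, sig, seed=42)
        assert f1.slope == f2.slope and f1.intercept == f2.intercept

    def test_constant_reference_rejected(self):
        with pytest.raises(FitError):
            fit_reference(np.ones(100), np.arange(100.0))


class TestReferenceSubtract:
    def test_identical_traces_cancel(self):
        x = np.sin(np.arange(100) / 5.0)
        fit = RansacFit(slope=1.0, intercept=0.0,
                        inlier_mask=np.ones(100, bool), n_iterations=0,
                        residual_threshold=0.0, min_samples=2, seed=0)
        dff, transformed = reference_subtract(x, fit, x)
        np.testing.assert_allclose(dff, 0.0, atol=1e-15)
        np.testing.assert_allclose(transformed, x)

    def test_zero_reference_identity(self):
        x = np.arange(50.0)
        fit = RansacFit(slope=1.0, intercept=0.0,
                        inlier_mask=np.ones(50, bool), n_iterations=0,
                        residual_threshold=0.0, min_samples=2, seed=0)
        dff, _ = reference_subtract(x, fit, np.zeros(50))
        np.testing.assert_array_equal(dff, x)


def make_qc_traces(max_pct, corr, n=4000, seed=0):
    """Construct (dff, reference) with exact max percent and correlation."""
    rng = np.random.default_rng(seed)
    u1 = np.sin(2 * np.pi * np.arange(n) / 250.0)
    u2 = rng.standard_normal(n)
    u1 = (u1 - u1.mean()) / np.linalg.norm(u1 - u1.mean())
    u2 = u2 - u2.mean()
    u2 -= u1 * (u1 @ u2)
    u2 /= np.linalg.norm(u2)
    dff = corr * u1 + np.sqrt(1 - corr ** 2) * u2
    dff = dff / dff.max() * (max_pct / 100.0)
    return dff, u1


class TestQCGate:
    @pytest.mark.parametrize("max_pct,corr,expected", [
        (2.0, 0.3, True),    # above amplitude, below correlation
        (1.0, 0.3, False),   # amplitude too small
        (5.0, 0.7, False),   # correlated with the reference
        (1.0, 0.7, False),   # fails both
    ])
    def test_inclusion_rule_quadrants(self, max_pct, corr, expected):
        dff, ref = make_qc_traces(max_pct, corr)
        res = qc_gate(dff, ref)
        assert res.passed is expected
        assert res.max_dff_percent == pytest.approx(max_pct, rel=1e-6)
        assert res.signal_reference_correlation == pytest.approx(corr, abs=1e-9)

    def test_constant_trace_degenerate_correlation(self):
        res = qc_gate(np.zeros(100), np.zeros(100))
        assert res.signal_reference_correlation == 0.0
        assert not res.passed


class TestChains:
    def test_null_session_dff_zero_and_qc_fails(self):
        params = SimParams(duration_s=20.0, sampling_rate=100.0,
                           noise_sd_signal=0.0, noise_sd_reference=0.0,
                           artifact_rate_per_min=0.0, rate_move_hz=0.0,
                           rate_rest_hz=0.0, move_mean_s=0.0,
                           bleach_signal=(0.0, 1.0, 1.0, np.inf),
                           bleach_reference=(0.0, 1.0, 1.0, np.inf))
        session, _ = simulate_photometry(params, seed=0)
        assert np.ptp(session.signal) == 0.0
        norm = normalize_gcamp(session)
        np.testing.assert_allclose(norm.dff, 0.0, atol=1e-12)
        np.testing.assert_allclose(norm.zscore, 0.0)
        assert not norm.qc.passed

    def test_patch_like_session_passes_qc(self, patch_norm):
        assert patch_norm.qc.passed
        assert patch_norm.qc.max_dff_percent > 1.5

    def test_artifact_dominated_session_fails_qc(self):
        # no transients at all: whatever survives referencing tracks the
        # reference, or the amplitude gate fails
        params = SimParams(duration_s=120.0, sampling_rate=100.0,
                           rate_move_hz=0.0, rate_rest_hz=0.0, move_mean_s=0.0,
                           artifact_rate_per_min=40.0, artifact_amp_sd=8.0,
                           noise_sd_signal=0.01, noise_sd_reference=0.01)
        session, _ = simulate_photometry(params, seed=5)
        norm = normalize_gcamp(session)
        assert not norm.qc.passed

    def test_common_scaling_leaves_dff_unchanged(self, patch_session):
        s = patch_session["session"]
        scaled = PhotometrySession(time=s.time, signal=3.0 * s.signal,
                                   reference=3.0 * s.reference,
                                   sampling_rate=s.sampling_rate,
                                   sensor_kind="gcamp")
        n1 = normalize_gcamp(s)
        n2 = normalize_gcamp(scaled)
        np.testing.assert_allclose(n2.dff, n1.dff, atol=1e-9)

    def test_zscore_session_invariant(self, patch_norm):
        z = patch_norm.zscore
        assert abs(z.mean()) < 1e-9
        assert abs(z.std() - 1.0) < 1e-9

    def test_wrong_sensor_kind_rejected(self, patch_session):
        with pytest.raises(ParameterError):
            normalize_rdam(patch_session["session"])
        s = patch_session["session"]
        rdam = PhotometrySession(time=s.time, signal=s.signal,
                                 reference=s.reference,
                                 sampling_rate=s.sampling_rate,
                                 sensor_kind="rdam")
        with pytest.raises(ParameterError):
            normalize_gcamp(rdam)


class TestRdamChain:
    def test_perfect_affine_reference_gives_zero_dff(self):
        n, fs = 2000, 100.0
        t = np.arange(n) / fs
        ref = 60.0 + 5.0 * np.sin(t / 3.0)
        session = PhotometrySession(time=t, signal=3.0 * ref, reference=ref,
                                    sampling_rate=fs, sensor_kind="rdam")
        norm = normalize_rdam(session)
        np.testing.assert_allclose(norm.dff, 0.0, atol=1e-9)

    def test_injected_suppression_visible_in_dff(self):
        from striatophot.synthetic import simulate_stim_session

        params = SimParams(sampling_rate=100.0, trials_per_duration=1,
                           stim_durations_s=(15.0,), stim_depth=-0.5,
                           noise_sd_signal=0.0, noise_sd_reference=0.0)
        session, truth = simulate_stim_session(params, seed=0)
        norm = normalize_rdam(session)
        on = truth.true_stim[0]["onset_s"]
        off = truth.true_stim[0]["offset_s"]
        i0, i1 = int((off - 1.0) * 100), int(off * 100)
        assert np.mean(norm.dff[i0:i1]) == pytest.approx(-0.5, abs=0.01)
        pre = norm.dff[int((on - 2.0) * 100):int(on * 100)]
        assert np.mean(pre) == pytest.approx(0.0, abs=0.01)


class TestArtifactRemoval:
    def test_referencing_removes_shared_artifact(self):
        from striatophot.synthetic import simulate_locomotion

        pre, post = [], []
        for seed in range(5):
            params = SimParams(duration_s=300.0, sampling_rate=100.0,
                               coupling_profile="none")
            vel, lt = simulate_locomotion(params, seed=seed)
            session, truth = simulate_photometry(params, velocity=vel, seed=seed,
                                                 true_bouts=lt.true_bouts)
            norm = normalize_gcamp(session)
            a = truth.true_artifact_trace
            pre.append(abs(np.corrcoef(norm.prenorm_signal, a)[0, 1]))
            post.append(abs(np.corrcoef(norm.dff, a)[0, 1]))
        assert min(pre) > 0.5
        assert max(post) < 0.15  # full 20-session study in the acceptance suite
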