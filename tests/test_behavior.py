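"""Bout segmentation rules, summaries and partition/monotonicity properties."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from striatophot import (BoutSet, ParameterError, SimParams, bout_summaries,
                         segment_immobility, segment_openfield_ambulation,
                         segment_treadmill, simulate_locomotion)
from striatophot.config import BoutConfig

from conftest import make_velocity

FS = 100.0


def steps(*segments, fs=FS):
    """Velocity from (duration_s, value) segments."""
    return make_velocity(np.concatenate(
        [np.full(int(round(d * fs)), v) for d, v in segments]), fs)


class TestTreadmill:
    def test_all_zero_velocity(self):
        bs = segment_treadmill(make_velocity(np.zeros(1000)))
        assert bs.of_kind("movement") == []
        rest = bs.of_kind("rest")
        assert len(rest) == 1
        assert rest[0].duration_s == pytest.approx(10.0)

    def test_fixed_schedule_recovered_exactly(self):
        params = SimParams(duration_s=30.0, sampling_rate=FS,
                           schedule=[(5.0, 8.0), (12.0, 20.0)],
                           rest_noise_cm_s=0.0, speed_jitter=0.0)
        vel, truth = simulate_locomotion(params, seed=0)
        bs = segment_treadmill(vel)
        moves = bs.of_kind("movement")
        assert len(moves) == 2
        for bout, (on, off) in zip(moves, truth.true_bouts):
            assert abs(bout.onset_s - on) <= 1.0 / FS + 1e-9
            assert abs(bout.offset_s - off) <= 1.0 / FS + 1e-9

    def test_short_blip_excluded(self):
        # a 0.4 s supra-threshold blip between long rests is flagged excluded
        vel = steps((5.0, 0.0), (0.4, 3.0), (5.0, 0.0))
        bs = segment_treadmill(vel)
        assert bs.of_kind("movement") == []
        flagged = bs.of_kind("movement", include_excluded=True)
        assert len(flagged) == 1 and flagged[0].excluded
        assert flagged[0].duration_s == pytest.approx(0.4, abs=1 / FS)

    def test_slow_movement_excluded(self):
        # long enough but mean velocity below 0.5 cm/s
        vel = steps((5.0, 0.0), (2.0, 0.4), (5.0, 0.0))
        bs = segment_treadmill(vel)
        assert bs.of_kind("movement") == []
        flagged = bs.of_kind("movement", include_excluded=True)
        assert len(flagged) == 1
        assert flagged[0].mean_velocity == pytest.approx(0.4)

    def test_short_dip_does_not_split_movement(self):
        # a 0.6 s sub-threshold dip (< 0.8 s) is absorbed, not a rest
        vel = steps((3.0, 0.0), (4.0, 3.0), (0.6, 0.1), (4.0, 3.0), (3.0, 0.0))
        bs = segment_treadmill(vel)
        moves = bs.of_kind("movement")
        assert len(moves) == 1
        assert moves[0].duration_s == pytest.approx(8.6, abs=2 / FS)

    def test_long_dip_splits_movement(self):
        vel = steps((3.0, 0.0), (4.0, 3.0), (1.0, 0.1), (4.0, 3.0), (3.0, 0.0))
        bs = segment_treadmill(vel)
        assert len(bs.of_kind("movement")) == 2

    def test_partition_covers_session(self, patch_session):
        bs = segment_treadmill(patch_session["velocity"])
        spans = sorted((b.onset_s, b.offset_s) for b in bs.bouts)
        assert spans[0][0] == pytest.approx(bs.t0)
        for (a0, a1), (b0, b1) in zip(spans, spans[1:]):
            assert b0 == pytest.approx(a1, abs=1e-9)
        assert spans[-1][1] == pytest.approx(bs.t0 + bs.session_duration_s)

    def test_signed_velocity_flag(self):
        vel = steps((3.0, 0.0), (2.0, -3.0), (3.0, 0.0))
        default = segment_treadmill(vel)  # absolute: backward walking counts
        assert len(default.of_kind("movement")) == 1
        cfg = BoutConfig(use_absolute_velocity=False)
        signed = segment_treadmill(vel, cfg)
        assert signed.of_kind("movement") == []


class TestAmbulation:
    def test_single_long_run(self):
        bs = segment_openfield_ambulation(steps((10.0, 5.0)))
        assert len(bs.bouts) == 1
        assert bs.bouts[0].duration_s == pytest.approx(10.0)

    def test_short_gap_merges(self):
        vel = steps((2.0, 0.0), (1.0, 5.0), (0.3, 0.5), (1.0, 5.0), (2.0, 0.0))
        bs = segment_openfield_ambulation(vel)
        assert len(bs.bouts) == 1
        assert bs.bouts[0].duration_s == pytest.approx(2.3, abs=2 / FS)

    def test_long_gap_separates(self):
        vel = steps((2.0, 0.0), (1.0, 5.0), (0.8, 0.5), (1.0, 5.0), (2.0, 0.0))
        bs = segment_openfield_ambulation(vel)
        assert len(bs.bouts) == 2

    def test_too_short_run_dropped(self):
        bs = segment_openfield_ambulation(steps((5.0, 0.0), (0.4, 5.0), (5.0, 0.0)))
        assert bs.bouts == []

    @given(st.integers(0, 2 ** 31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_raising_threshold_never_increases_time(self, seed):
        rng = np.random.default_rng(seed)
        vel = make_velocity(np.abs(rng.normal(2.0, 2.0, 600)))
        low = BoutConfig(ambulation_threshold_cm_s=1.5)
        high = BoutConfig(ambulation_threshold_cm_s=3.0)
        t_low = sum(b.duration_s for b in segment_openfield_ambulation(vel, low).bouts)
        t_high = sum(b.duration_s for b in segment_openfield_ambulation(vel, high).bouts)
        assert t_high <= t_low + 1e-9


class TestImmobility:
    def test_all_quiet(self):
        bs = segment_immobility(np.zeros(300), FS)
        assert len(bs.bouts) == 1
        assert bs.bouts[0].duration_s == pytest.approx(3.0)

    def test_alternating_activity(self):
        act = np.concatenate([np.full(60, 1.0), np.full(60, 5.0)] * 4)
        bs = segment_immobility(act, FS)
        assert len(bs.bouts) == 4
        for b in bs.bouts:
            assert b.duration_s == pytest.approx(0.6, abs=2 / FS)

    def test_short_quiet_run_dropped(self):
        act = np.concatenate([np.full(300, 5.0), np.full(40, 1.0),
                              np.full(300, 5.0)])
        bs = segment_immobility(act, FS)
        assert bs.bouts == []

    def test_velocity_proxy_flagged(self):
        bs = segment_immobility(np.zeros(100), FS, is_velocity_proxy=True)
        assert bs.meta["velocity_proxy"] is True


class TestSummaries:
    def test_arithmetic(self):
        from striatophot.behavior import Bout

        bs = BoutSet(bouts=[Bout(1.0, 2.0, "ambulation", 5.0),
                            Bout(5.0, 6.0, "ambulation", 3.0)],
                     session_duration_s=10.0)
        s = bout_summaries(bs, "ambulation")
        assert s["frequency_hz"] == pytest.approx(0.2)
        assert s["percent_time"] == pytest.approx(20.0)
        assert s["mean_duration_s"] == pytest.approx(1.0)
        assert s["mean_velocity_cm_s"] == pytest.approx(4.0)

    def test_empty(self):
        bs = BoutSet(bouts=[], session_duration_s=10.0)
        s = bout_summaries(bs, "movement")
        assert s["n_bouts"] == 0 and s["frequency_hz"] == 0.0
        assert s["percent_time"] == 0.0
        assert np.isnan(s["mean_duration_s"])

    def test_window_clipping(self):
        from striatophot.behavior import Bout

        bs = BoutSet(bouts=[Bout(0.0, 4.0, "movement", 2.0)],
                     session_duration_s=10.0)
        s = bout_summaries(bs, "movement", window=(2.0, 6.0))
        assert s["percent_time"] == pytest.approx(50.0)

    def test_empty_window_rejected(self):
        bs = BoutSet(bouts=[], session_duration_s=10.0)
        with pytest.raises(ParameterError):
            bout_summaries(bs, "movement", window=(5.0, 5.0))

    def test_schedule_derived_values(self):
        params = SimParams(duration_s=30.0, sampling_rate=FS,
                           schedule=[(5.0, 8.0), (12.0, 20.0)],
                           rest_noise_cm_s=0.0, speed_jitter=0.0)
        vel, _ = simulate_locomotion(params, seed=0)
        s = bout_summaries(segment_treadmill(vel), "movement")
        assert s["n_bouts"] == 2
        assert s["percent_time"] == pytest.approx(11.0 / 30.0 * 100.0, rel=0.01)


class TestIdempotence:
    def test_resegmenting_reconstructed_trace(self, patch_session):
        bs = segment_treadmill(patch_session["velocity"])
        fs = patch_session["velocity"].sampling_rate
        n = patch_session["velocity"].velocity.size
        rebuilt = np.zeros(n)
        for b in bs.of_kind("movement"):
            i0, i1 = int(round(b.onset_s * fs)), int(round(b.offset_s * fs))
            rebuilt[i0:i1] = b.mean_velocity
        bs2 = segment_treadmill(make_velocity(rebuilt, fs))
        on1, on2 = bs.onsets("movement"), bs2.onsets("movement")
        assert on1.size == on2.size
        np.testing.assert_allclose(on1, on2, atol=1.0 / fs)
        np.testing.assert_allclose(bs.offsets("movement"), bs2.offsets("movement"),
                                   atol=1.0 / fs)
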