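"""PTT extraction chain: beat-wise PTT, PTT2 smoothing, spike masking,
arousal detection, the derived respiratory channel and PTTrs."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pttsleep import ptt as P
from pttsleep import synth
from conftest import make_beats, make_dip_series


def _pulse_waveform(foot_times, fs=100.0, total=None, upstroke=0.15):
    """Pleth made of raised-cosine upstrokes + exponential decays."""
    total = total or (max(foot_times) + 2.0)
    n = int(total * fs)
    y = np.zeros(n)
    for i, ft in enumerate(foot_times):
        i0 = int(np.ceil(ft * fs))
        i1 = min(int(np.ceil((ft + upstroke) * fs)), n)
        tt = np.arange(i0, i1) / fs
        y[i0:i1] = 0.5 * (1 - np.cos(np.pi * (tt - ft) / upstroke))
        nxt = foot_times[i + 1] if i + 1 < len(foot_times) else ft + 1.2
        j1 = min(int(np.ceil(nxt * fs)), n)
        td = np.arange(i1, j1) / fs
        y[i1:j1] = np.exp(-(td - ft - upstroke) / 0.25)
    return y


class TestComputePtt:
    def test_constructed_half_amplitude_crossing(self):
        # pulse foot at 10.175 s -> 50% crossing at 10.250 s -> PTT 250 ms
        pleth = _pulse_waveform([10.175], total=12.0)
        beats = P.compute_ptt(np.array([10.0]), pleth, 100.0)
        assert beats.ptt_raw[0] == pytest.approx(250.0, abs=2.0)
        assert beats.valid[0]

    def test_validity_floor_at_150_ms(self):
        # crossing at +120 ms is outside the 150-500 ms band
        pleth = _pulse_waveform([10.045], total=12.0)
        beats = P.compute_ptt(np.array([10.0]), pleth, 100.0)
        assert beats.ptt_raw[0] == pytest.approx(120.0, abs=2.0)
        assert not beats.valid[0]

    def test_programmed_delays_recovered_within_sample_period(self, rng):
        r = 0.5 + np.arange(1000) * 0.6
        delays = rng.uniform(0.200, 0.300, size=1000)
        feet = r + delays - 0.075
        pleth = _pulse_waveform(feet, total=r[-1] + 2.0)
        beats = P.compute_ptt(r, pleth, 100.0)
        err = np.abs(beats.ptt_raw - delays * 1000.0)
        assert np.nanmax(err) <= 10.0  # one pleth sample period
        assert beats.valid.all()

    def test_dropout_marks_beat_invalid_not_raises(self):
        pleth = _pulse_waveform([10.175], total=30.0)
        beats = P.compute_ptt(np.array([10.0, 20.0]), pleth, 100.0)
        assert beats.valid[0] and not beats.valid[1]
        assert np.isnan(beats.ptt_raw[1])

    def test_empty_inputs_error(self):
        with pytest.raises(ValueError):
            P.compute_ptt(np.array([]), np.zeros(100), 100.0)


class TestSmoothPtt2:
    def test_constant_series_invariant(self):
        t = np.arange(100) * 0.6
        out = P.smooth_ptt2(make_beats(t, np.full(100, 250.0)))
        assert np.allclose(out, 250.0)

    def test_impulse_response_of_17_point_mean(self):
        x = np.full(101, 250.0)
        x[50] = 267.0
        out = P.smooth_ptt2(make_beats(np.arange(101) * 0.6, x))
        assert out[50] == pytest.approx(251.0)  # 250 + 17/17

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=25, deadline=None)
    def test_matches_brute_force_windowed_mean(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 80))
        x = rng.uniform(150, 500, n)
        valid = rng.random(n) > 0.2
        beats = make_beats(np.arange(n) * 0.6, x, valid)
        out = P.smooth_ptt2(beats)
        for i in range(n):
            w = slice(max(0, i - 8), min(n, i + 9))
            sel = valid[w]
            if sel.any():
                assert out[i] == pytest.approx(np.mean(x[w][sel]))
            else:
                assert np.isnan(out[i])


class TestArtefactRemoval:
    def test_smooth_channel_nothing_masked(self):
        t = np.arange(0, 3600, 0.6)
        x = 250 + 10 * np.sin(2 * np.pi * t / 4)
        iv, mask, hours = P.remove_ptt_artefact(make_beats(t, x), duration=3600)
        assert iv == [] and not mask.any()
        assert hours == pytest.approx(1.0)

    def test_single_spike_masked_with_guard(self):
        t = np.arange(0, 4 * 3600, 0.6)
        x = np.full_like(t, 250.0)
        spike = (t >= 7200) & (t < 7205)
        x[spike] += 120.0
        iv, mask, hours = P.remove_ptt_artefact(make_beats(t, x),
                                                duration=4 * 3600)
        masked = sum(e - s for s, e in iv)
        assert masked == pytest.approx(5 + 2 * P.SPIKE_GUARD_S, abs=2.5)
        assert hours == pytest.approx(4 - masked / 3600, abs=1e-6)
        assert all(s <= 7200 <= e or s <= 7205 <= e for s, e in iv)


class TestArousalDetection:
    @pytest.mark.parametrize("depth,fall,expected", [
        (20.0, 10.0, 1),   # canonical arousal
        (15.0, 10.0, 1),   # threshold is inclusive
        (14.0, 10.0, 0),   # just below the 15 ms rule
        (20.0, 60.0, 0),   # develops too slowly (outside 5-45 s)
        (20.0, 2.0, 0),    # too fast to be physiological
    ])
    def test_dip_fixtures_straddle_the_rule(self, depth, fall, expected):
        t, x = make_dip_series(depth, fall)
        events, _ = P.detect_ptt_arousals(make_beats(t, x), x,
                                          artefact_free_hours=t[-1] / 3600)
        assert len(events) == expected

    def test_constant_and_monotone_series_have_no_events(self):
        t = np.arange(0, 600, 0.6)
        for x in (np.full_like(t, 250.0), 250 + 0.05 * t):
            events, _ = P.detect_ptt_arousals(make_beats(t, x), x,
                                              artefact_free_hours=0.1)
            assert events == []

    def test_event_count_invariant_under_constant_shift(self):
        t, x = make_dip_series(25.0, 12.0)
        for shift in (0.0, 40.0, -30.0):
            events, _ = P.detect_ptt_arousals(make_beats(t, x + shift), x + shift,
                                              artefact_free_hours=0.1)
            assert len(events) == 1

    def test_out_of_range_ptt2_not_counted(self):
        # same dip shape but parked above the 500 ms validity ceiling
        t, x = make_dip_series(25.0, 12.0, baseline=540.0)
        events, _ = P.detect_ptt_arousals(make_beats(t, x), x,
                                          artefact_free_hours=0.1)
        assert events == []

    def test_ptt_ai_is_count_over_hours(self):
        t, x = make_dip_series(25.0, 12.0)
        events, ai = P.detect_ptt_arousals(make_beats(t, x), x,
                                           artefact_free_hours=0.5)
        assert ai == len(events) / 0.5

    def test_zero_hours_flags_undefined_index(self):
        t, x = make_dip_series(25.0, 12.0)
        _, ai = P.detect_ptt_arousals(make_beats(t, x), x,
                                      artefact_free_hours=0.0)
        assert np.isnan(ai)


class TestRespChannel:
    def test_constant_beats_give_constant_channel(self):
        t = np.arange(0, 60, 0.6)
        grid, resp, mask = P.derive_resp_channel(t, np.full_like(t, 250.0),
                                                 np.ones_like(t, bool))
        assert np.allclose(resp[~mask], 250.0)

    def test_linear_interpolation_midpoint(self):
        grid, resp, mask = P.derive_resp_channel(
            np.array([0.0, 2.0]), np.array([240.0, 260.0]),
            np.array([True, True]), duration=2.0)
        # interpolated values 240/250/260; 3-sample mean at t=1 stays 250
        assert resp[1] == pytest.approx(250.0)

    def test_three_sample_mean_gain_at_period_four(self):
        # closed form: |1 + 2 cos(2*pi/4)| / 3 = 1/3 for a 4 s sinusoid
        t = np.arange(0.0, 600.0)
        x = 250 + 10 * np.sin(2 * np.pi * t / 4)
        grid, resp, mask = P.derive_resp_channel(t, x, np.ones_like(t, bool))
        amp = (resp[5:-5].max() - resp[5:-5].min()) / 2
        assert amp == pytest.approx(10 / 3, rel=0.02)

    def test_requires_two_valid_beats(self):
        with pytest.raises(ValueError):
            P.derive_resp_channel(np.array([1.0]), np.array([250.0]),
                                  np.array([True]))

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None)
    def test_matches_brute_force_interp_and_mean(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 60))
        t = np.sort(rng.uniform(0, 60, n))
        t = t[np.concatenate(([True], np.diff(t) > 1e-3))]
        x = rng.uniform(200, 300, t.size)
        grid, resp, mask = P.derive_resp_channel(t, x, np.ones(t.size, bool))
        interp = np.interp(grid, t, x)
        for i in range(1, grid.size - 1):
            assert resp[i] == pytest.approx(interp[i - 1:i + 2].mean())


class TestPttrs:
    def test_flat_channel_is_zero_with_flag(self):
        res = P.compute_pttrs(np.full(300, 250.0))
        assert res.pttrs == 0.0 and res.no_breaths

    def test_sinusoid_amplitude_10_gives_20(self):
        t = np.arange(0.0, 400.0)
        x = 250 + 10 * np.sin(2 * np.pi * t / 4 + np.pi / 2)
        res = P.compute_pttrs(x)
        assert res.pttrs == pytest.approx(20.0, rel=0.01)

    @given(st.floats(0.5, 4.0), st.floats(-50, 50))
    @settings(max_examples=20, deadline=None)
    def test_scale_equivariant_and_shift_invariant(self, k, shift):
        t = np.arange(0.0, 300.0)
        base = 10 * np.sin(2 * np.pi * t / 5.3) + 2 * np.sin(2 * np.pi * t / 17)
        r0 = P.compute_pttrs(250 + base)
        r1 = P.compute_pttrs(250 + shift + k * base)
        assert r1.pttrs == pytest.approx(k * r0.pttrs, rel=1e-6)

    def test_masked_samples_excluded(self):
        t = np.arange(0.0, 200.0)
        x = 250 + 10 * np.sin(2 * np.pi * t / 4 + np.pi / 2)
        mask = np.zeros(t.size, bool)
        mask[100:] = True
        x[100:] = 250 + 40 * np.sin(2 * np.pi * t[100:] / 4 + np.pi / 2)
        res = P.compute_pttrs(x, mask)
        assert res.pttrs == pytest.approx(20.0, rel=0.02)


class TestDurationRule:
    @pytest.mark.parametrize("hours,min_hours,included", [
        (2.9, 3.0, False),
        (3.0, 3.0, True),     # boundary inclusive: the exclusion is "< 3 h"
        (3.5, 4.0, False),
        (4.0, 4.0, True),
    ])
    def test_boundaries(self, hours, min_hours, included):
        assert P.apply_duration_rule(hours, min_hours) is included

    def test_negative_hours_error(self):
        with pytest.raises(ValueError):
            P.apply_duration_rule(-0.1)

    def test_four_hour_subset_nested_in_three_hour_subset(self, rng):
        hours = rng.normal(4.79, 1.32, 200)
        keep3 = {i for i, h in enumerate(hours) if h >= 0 and P.apply_duration_rule(max(h, 0), 3)}
        keep4 = {i for i, h in enumerate(hours) if h >= 0 and P.apply_duration_rule(max(h, 0), 4)}
        assert keep4 <= keep3
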