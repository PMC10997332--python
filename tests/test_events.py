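"""Onset detection, alignment, baselining, triggered averages."""

import numpy as np
import pandas as pd
import pytest

from corticoflow import events as ev
from corticoflow import synth
from corticoflow.session import Session

from conftest import naive_onset_scan


def _step_trace(n, fs, t_step, value, t_end=None):
    x = np.zeros(n)
    i0 = int(round(t_step * fs))
    i1 = n if t_end is None else int(round(t_end * fs))
    x[i0:i1] = value
    return x


class TestDetectOnsets:
    def test_zero_speed_yields_empty_table(self):
        table = ev.detect_onsets(np.zeros(1000), np.zeros(1000), 100.0)
        assert len(table) == 0

    def test_single_step_gives_one_valid_onset(self):
        fs = 100.0
        primary = _step_trace(2000, fs, 5.0, 40.0)
        table = ev.detect_onsets(primary, np.zeros(2000), fs)
        assert len(table) == 1
        assert table.iloc[0]["valid"]
        assert table.iloc[0]["time_s"] == pytest.approx(5.0)

    def test_second_crossing_invalid_with_reason(self):
        fs = 100.0
        primary = np.zeros(3000)
        primary[500:700] = 40.0   # first bout at 5 s
        primary[700:900] = 10.0   # still moving (above quiescence)
        primary[900:1100] = 40.0  # re-crossing 2 s later
        table = ev.detect_onsets(primary, np.zeros(3000), fs)
        assert len(table) == 2
        assert table.iloc[0]["valid"]
        assert not table.iloc[1]["valid"]
        assert table.iloc[1]["exclusion_reason"] == "activity in pre-window"

    def test_flow_activity_in_prewindow_invalidates_locomotion_onset(self):
        fs = 100.0
        primary = _step_trace(2000, fs, 10.0, 40.0)
        other = _step_trace(2000, fs, 8.0, 5.0, t_end=9.0)
        table = ev.detect_onsets(primary, other, fs)
        assert not table.iloc[0]["valid"]

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths differ"):
            ev.detect_onsets(np.zeros(100), np.zeros(99), 100.0)

    def test_matches_bruteforce_scan_on_random_bout_traces(self, small_cfg):
        for seed in range(20):
            rng = np.random.default_rng(seed)
            speed = synth.simulate_locomotion(60.0, small_cfg, rng)
            other = synth.simulate_locomotion(60.0, small_cfg, rng)
            table = ev.detect_onsets(speed, other, small_cfg.fs_hz)
            expected = naive_onset_scan(speed, other, small_cfg.fs_hz,
                                        30.0, 3.0, 1.0)
            got = list(zip(table["time_s"], table["valid"],
                           table["exclusion_reason"]))
            assert got == expected


def _toy_session(traces, fs=100.0, mouse="m0"):
    n = traces.shape[1]
    return Session(traces=traces, roi_ids=[f"r{i}"
                                           for i in range(traces.shape[0])],
                   speed=np.zeros(n), flow=np.zeros(n), fs_hz=fs,
                   mouse_id=mouse, session_id="s0", condition="dark")


def _events_at(times, etype="loco_dark"):
    return pd.DataFrame({"time_s": times, "type": etype, "valid": True,
                         "exclusion_reason": ""})


class TestExtractAligned:
    def test_window_arithmetic(self):
        fs = 100.0
        traces = np.arange(30000, dtype=float)[None, :] / fs
        s = _toy_session(traces, fs)
        aligned = ev.extract_aligned(s, _events_at([100.0]),
                                     window_s=(-5.0, 3.0))
        assert aligned.data.shape == (1, 1, 800)
        # snippet covers 95 s .. 103 s of session time
        assert aligned.data[0, 0, 0] == pytest.approx(95.0)
        assert aligned.data[0, 0, -1] == pytest.approx(103.0 - 1 / fs)

    def test_event_too_close_to_edge_dropped(self):
        s = _toy_session(np.zeros((2, 3000)))
        aligned = ev.extract_aligned(s, _events_at([2.0, 15.0]),
                                     window_s=(-5.0, 3.0))
        assert aligned.n_onsets == 1
        assert aligned.n_dropped == 1

    def test_constant_trace_gives_constant_snippets(self):
        s = _toy_session(np.full((3, 3000), 0.7))
        aligned = ev.extract_aligned(s, _events_at([10.0, 20.0]),
                                     window_s=(-2.0, 1.0))
        np.testing.assert_allclose(aligned.data, 0.7)

    def test_no_usable_events_is_empty_not_error(self):
        s = _toy_session(np.zeros((2, 3000)))
        aligned = ev.extract_aligned(s, _events_at([]), window_s=(-5, 3))
        assert aligned.n_onsets == 0


class TestBaselineSubtract:
    @pytest.mark.parametrize("mode,window", [
        ("stimulus", (-0.2, 0.0)),
        ("onset_gcamp", (-2.9, -2.7)),
        ("onset_egfp", (-0.9, -0.7)),
    ])
    def test_mode_window_and_exact_zero_mean(self, mode, window, rng):
        aligned = ev.AlignedResponses(
            data=rng.normal(size=(7, 3, 800)), roi_ids=["a", "b", "c"],
            window_s=(-5.0, 3.0), bin_s=0.01,
            mouse_labels=np.array(["m"] * 7),
            onset_times_s=np.arange(7, dtype=float))
        out = ev.baseline_subtract(aligned, mode)
        assert out.baseline_window_s == window
        t = out.time_s
        mask = (t >= window[0] - 1e-9) & (t < window[1] - 1e-9)
        means = out.data[:, :, mask].mean(axis=2)
        np.testing.assert_allclose(means, 0.0, atol=1e-14)

    def test_idempotent(self, rng):
        aligned = ev.AlignedResponses(
            data=rng.normal(size=(4, 2, 800)), roi_ids=["a", "b"],
            window_s=(-5.0, 3.0), bin_s=0.01,
            mouse_labels=np.array(["m"] * 4),
            onset_times_s=np.arange(4, dtype=float))
        once = ev.baseline_subtract(aligned, "onset_gcamp")
        twice = ev.baseline_subtract(once, "onset_gcamp")
        np.testing.assert_allclose(twice.data, once.data, atol=1e-12)

    def test_window_outside_range_names_mode(self, rng):
        aligned = ev.AlignedResponses(
            data=rng.normal(size=(2, 1, 100)), roi_ids=["a"],
            window_s=(-0.5, 0.5), bin_s=0.01,
            mouse_labels=np.array(["m"] * 2),
            onset_times_s=np.arange(2, dtype=float))
        with pytest.raises(ValueError, match="onset_gcamp"):
            ev.baseline_subtract(aligned, "onset_gcamp")


def _aligned_from(data, mice):
    n_onsets, n_roi, n_bins = data.shape
    return ev.AlignedResponses(
        data=data, roi_ids=[f"r{i}" for i in range(n_roi)],
        window_s=(-1.0, 1.0), bin_s=2.0 / n_bins,
        mouse_labels=np.asarray(mice, dtype=object),
        onset_times_s=np.arange(n_onsets, dtype=float))


class TestTriggeredAverage:
    def test_zero_variance_gives_zero_width_band(self):
        data = np.tile(np.linspace(0, 1, 50), (6, 2, 1))
        aligned = _aligned_from(data, ["m0", "m0", "m0", "m1", "m1", "m1"])
        resp = ev.triggered_average(aligned, n_boot=200, seed=0)
        np.testing.assert_allclose(resp.ci_low, resp.mean, atol=1e-12)
        np.testing.assert_allclose(resp.ci_high, resp.mean, atol=1e-12)

    def test_two_constant_mice_band_inside_their_values(self):
        # mouse resamples give means in {a, (a+b)/2, b}; the 90% band of
        # the replicate distribution must stay inside [a, b]
        a_val, b_val = 1.0, 3.0
        data = np.concatenate([np.full((5, 1, 20), a_val),
                               np.full((5, 1, 20), b_val)])
        aligned = _aligned_from(data, ["a"] * 5 + ["b"] * 5)
        resp = ev.triggered_average(aligned, n_boot=500, seed=1)
        assert np.all(resp.ci_low >= a_val - 1e-12)
        assert np.all(resp.ci_high <= b_val + 1e-12)
        np.testing.assert_allclose(resp.mean, 2.0)

    def test_invariant_to_onset_order_and_mouse_relabelling(self, rng):
        data = rng.normal(size=(8, 2, 30))
        mice = ["m0"] * 4 + ["m1"] * 4
        a = ev.triggered_average(_aligned_from(data, mice), n_boot=300,
                                 seed=7)
        perm = rng.permutation(8)
        relabel = {"m0": "x9", "m1": "x1"}
        b = ev.triggered_average(
            _aligned_from(data[perm], [relabel[mice[p]] for p in perm]),
            n_boot=300, seed=7)
        np.testing.assert_allclose(a.mean, b.mean, atol=1e-12)

    def test_single_mouse_downgrades_to_flat_bootstrap(self, rng):
        data = rng.normal(size=(6, 1, 10))
        resp = ev.triggered_average(_aligned_from(data, ["m"] * 6),
                                    n_boot=200, seed=0)
        assert resp.band == "boot"


class TestLinearSum:
    def _resp(self, per_mouse, mice):
        per_mouse = np.asarray(per_mouse, dtype=float)
        mean = per_mouse.mean(axis=0)
        return ev.TriggeredResponse(
            mean=mean, ci_low=mean, ci_high=mean, roi_ids=["r0"],
            time_s=np.arange(per_mouse.shape[2], dtype=float),
            n_onsets=len(mice), n_mice=len(mice), mouse_ids=list(mice),
            per_mouse=per_mouse)

    def test_additive_identity(self):
        a = self._resp(np.random.default_rng(0).normal(size=(2, 1, 5)),
                       ["m0", "m1"])
        zero = self._resp(np.zeros((2, 1, 5)), ["m0", "m1"])
        out = ev.linear_sum(a, zero)
        np.testing.assert_allclose(out.mean, a.per_mouse.mean(axis=0))

    def test_hand_computed_mean_and_sem(self):
        # per-mouse sums (1+2, 3+4) = (3, 7): mean 5, SEM 2
        a = self._resp(np.array([[[1.0] * 4], [[3.0] * 4]]), ["m0", "m1"])
        b = self._resp(np.array([[[2.0] * 4], [[4.0] * 4]]), ["m0", "m1"])
        out = ev.linear_sum(a, b)
        np.testing.assert_allclose(out.mean, 5.0)
        np.testing.assert_allclose(out.ci_high - out.mean, 2.0)

    def test_commutative(self, rng):
        a = self._resp(rng.normal(size=(3, 1, 6)), ["m0", "m1", "m2"])
        b = self._resp(rng.normal(size=(3, 1, 6)), ["m0", "m1", "m2"])
        ab = ev.linear_sum(a, b)
        ba = ev.linear_sum(b, a)
        np.testing.assert_allclose(ab.mean, ba.mean, atol=1e-12)

    def test_mismatched_mouse_sets_listed(self):
        a = self._resp(np.zeros((2, 1, 4)), ["m0", "m1"])
        b = self._resp(np.zeros((2, 1, 4)), ["m0", "m2"])
        with pytest.raises(ValueError, match="m1.*m2"):
            ev.linear_sum(a, b)


class TestResponseMap:
    def test_uniform_movie_maps_to_zero(self):
        movie = np.full((2000, 4, 4), 0.3)
        events = _events_at([5.0, 10.0], etype="mismatch")
        out = ev.response_map(movie, events, fs_hz=100.0)
        np.testing.assert_allclose(out, 0.0, atol=1e-14)

    def test_single_responding_pixel_localised(self):
        fs = 100.0
        movie = np.zeros((3000, 3, 3))
        for t in (10.0, 20.0):
            i = int(t * fs)
            movie[i:i + 50, 1, 2] = 1.0
        out = ev.response_map(movie, _events_at([10.0, 20.0], "mismatch"),
                              fs_hz=fs)
        assert out[1, 2] > 0.4
        mask = np.ones((3, 3), dtype=bool)
        mask[1, 2] = False
        np.testing.assert_allclose(out[mask], 0.0, atol=1e-12)

    def test_known_amplitude_field_recovered(self, rng):
        fs = 50.0
        field = rng.uniform(0.1, 1.0, size=(4, 4))
        movie = rng.normal(0, 0.02, size=(6000, 4, 4))
        times = [20.0, 50.0, 80.0]
        for t in times:
            i = int(t * fs)
            movie[i:i + 50] += field
        out = ev.response_map(movie, _events_at(times, "mismatch"),
                              fs_hz=fs)
        np.testing.assert_allclose(out, field, atol=0.02)

    def test_no_events_is_error(self):
        with pytest.raises(ValueError, match="no valid events"):
            ev.response_map(np.zeros((100, 2, 2)), _events_at([]), 100.0)
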