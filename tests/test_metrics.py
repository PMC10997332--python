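"""Similarity, speed-activity and pairwise correlations, density, drug change."""

import numpy as np
import pandas as pd
import pytest

from corticoflow import metrics as mx
from corticoflow.events import TriggeredResponse
from corticoflow.geometry import RoiGeometry, default_geometry
from corticoflow.session import Session


def _resp(mean, roi_ids, time_s):
    mean = np.asarray(mean, dtype=float)
    return TriggeredResponse(mean=mean, ci_low=mean, ci_high=mean,
                             roi_ids=roi_ids, time_s=time_s,
                             n_onsets=10, n_mice=2)


def _time(pre=-5.0, post=3.0, bin_s=0.01):
    return pre + np.arange(int(round((post - pre) / bin_s))) * bin_s


class TestOnsetSimilarity:
    def test_identical_averages_give_unit_similarity(self, rng):
        t = _time()
        mean = rng.normal(size=(3, t.size))
        sim = mx.onset_similarity(_resp(mean, ["a", "b", "c"], t),
                                  _resp(mean.copy(), ["a", "b", "c"], t))
        np.testing.assert_allclose(sim.per_roi.values, 1.0, atol=1e-12)

    def test_sign_flip_gives_minus_one(self, rng):
        t = _time()
        mean = rng.normal(size=(2, t.size))
        sim = mx.onset_similarity(_resp(mean, ["a", "b"], t),
                                  _resp(-mean, ["a", "b"], t))
        np.testing.assert_allclose(sim.per_roi.values, -1.0, atol=1e-12)

    def test_symmetric_in_arguments(self, rng):
        t = _time()
        a = _resp(rng.normal(size=(2, t.size)), ["a", "b"], t)
        b = _resp(rng.normal(size=(2, t.size)), ["a", "b"], t)
        s1 = mx.onset_similarity(a, b)
        s2 = mx.onset_similarity(b, a)
        np.testing.assert_allclose(s1.per_roi.values, s2.per_roi.values,
                                   atol=1e-12)

    def test_matches_direct_pearson_on_smoothed_pair(self):
        # ramp vs ramp + orthogonal sinusoid: compute the expected r by
        # applying the same boxcar and Pearson formula directly
        t = _time()
        ramp = np.linspace(0, 1, t.size)
        sine = np.sin(2 * np.pi * 2.0 * (t - t[0]))
        sine -= sine.mean()
        sine -= (sine @ ramp) / (ramp @ ramp) * ramp  # orthogonalise
        sine *= ramp.std() / sine.std()
        other = ramp + sine
        sim = mx.onset_similarity(_resp(ramp[None, :], ["a"], t),
                                  _resp(other[None, :], ["a"], t),
                                  smooth_s=1.0)
        a = mx.boxcar_smooth(ramp, 100)
        b = mx.boxcar_smooth(other, 100)
        expected = np.corrcoef(a, b)[0, 1]
        assert sim.per_roi["a"] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_trace_reported_missing(self):
        t = _time()
        flat = np.zeros((1, t.size))
        wavy = np.sin(t)[None, :]
        sim = mx.onset_similarity(_resp(flat, ["a"], t),
                                  _resp(wavy, ["a"], t))
        assert np.isnan(sim.per_roi["a"])


class TestPerMouseV1Similarity:
    def _avgs(self, closed_traces, open_traces, t):
        rois = ["V1_L", "V1_R"]
        return {"closed": _resp(closed_traces, rois, t),
                "open": _resp(open_traces, rois, t)}

    def test_identical_responses_give_unit_r(self):
        t = _time()
        trc = np.vstack([np.sin(t) * 0.05, np.cos(t) * 0.05])
        table = mx.per_mouse_v1_similarity(
            {"m0": self._avgs(trc, trc.copy(), t)})
        row = table.iloc[0]
        assert row.r == pytest.approx(1.0)
        assert not row.excluded

    def test_weak_response_excluded(self):
        t = _time()
        strong = np.vstack([np.sin(t) * 0.05, np.sin(t) * 0.05])
        weak = strong * 0.1  # peak 0.5% dF/F < 1%
        table = mx.per_mouse_v1_similarity(
            {"m0": self._avgs(strong, weak, t)})
        row = table.iloc[0]
        assert row.excluded
        assert "open" in row.reason

    def test_hemisphere_average(self):
        t = _time()
        # construct hemispheres with known r = 1 (left) and r = -1 (right)
        closed = np.vstack([np.sin(t) * 0.05, np.sin(t) * 0.05])
        opened = np.vstack([np.sin(t) * 0.05, -np.sin(t) * 0.05])
        table = mx.per_mouse_v1_similarity(
            {"m0": self._avgs(closed, opened, t)})
        assert table.iloc[0].r == pytest.approx(0.0, abs=1e-9)

    def test_missing_condition_excluded_with_reason(self):
        t = _time()
        trc = np.zeros((2, t.size))
        table = mx.per_mouse_v1_similarity(
            {"m0": {"closed": _resp(trc, ["V1_L", "V1_R"], t)}})
        row = table.iloc[0]
        assert row.excluded and "open" in row.reason


def _session_from_traces(traces, roi_ids, speed=None, fs=100.0,
                         mouse="m0", sid="s0"):
    n = traces.shape[1]
    return Session(traces=traces, roi_ids=roi_ids,
                   speed=np.zeros(n) if speed is None else speed,
                   flow=np.zeros(n), fs_hz=fs, mouse_id=mouse,
                   session_id=sid, condition="dark")


class TestSpeedActivityCorrelation:
    def test_activity_equal_to_speed_gives_unit_r(self, rng):
        speed = np.abs(rng.normal(size=2000)) * 10
        s = _session_from_traces(speed[None, :], ["r0"], speed=speed)
        r = mx.speed_activity_correlation(s)
        assert r["r0"] == pytest.approx(1.0)

    def test_independent_noise_concentrates_near_zero(self):
        rs = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            speed = np.abs(rng.normal(size=1000))
            act = rng.normal(size=(1, 1000))
            s = _session_from_traces(act, ["r0"], speed=speed)
            rs.append(mx.speed_activity_correlation(s)["r0"])
        assert abs(np.mean(rs)) < 0.1

    def test_constant_speed_yields_missing(self):
        s = _session_from_traces(np.random.default_rng(0)
                                 .normal(size=(2, 500)), ["a", "b"])
        assert mx.speed_activity_correlation(s).isna().all()

    def test_session_averaging_to_mouse_level(self):
        frame = pd.DataFrame([
            {"mouse": "m0", "session": "s0", "condition": "dark",
             "roi": "V1_L", "r": 0.2},
            {"mouse": "m0", "session": "s1", "condition": "dark",
             "roi": "V1_L", "r": 0.4},
        ])
        agg = mx.aggregate_speed_correlation(frame)
        assert agg.iloc[0].r == pytest.approx(0.3)


class TestPairwiseRoiCorrelation:
    def test_identical_traces_give_unit_r_for_all_66_pairs(self, geometry):
        base = np.sin(np.linspace(0, 20, 3000))
        traces = np.tile(base, (12, 1))
        s = _session_from_traces(traces, geometry.roi_ids)
        pairs = mx.pairwise_roi_correlation(s, geometry)
        assert len(pairs) == 66
        np.testing.assert_allclose(pairs["r"], 1.0)

    def test_bregma_lambda_pair_has_unit_distance(self):
        geo = RoiGeometry({"bregma_roi": (0.0, 0.0),
                           "lambda_roi": (0.0, -4.2)},
                          bregma_lambda_mm=4.2)
        assert geo.d_norm("bregma_roi", "lambda_roi") == pytest.approx(1.0)

    def test_antiphase_rois_give_minus_one(self, geometry):
        t = np.linspace(0, 20, 3000)
        traces = np.tile(np.sin(t), (12, 1))
        traces[1] = -np.sin(t)
        s = _session_from_traces(traces, geometry.roi_ids)
        pairs = mx.pairwise_roi_correlation(s, geometry)
        # trace row 1 is V1_R in the default layout
        row = pairs[(pairs.roi_a == "V1_L") & (pairs.roi_b == "V1_R")].iloc[0]
        assert row.r == pytest.approx(-1.0)

    def test_zero_variance_roi_flagged_missing(self, geometry):
        traces = np.random.default_rng(0).normal(size=(12, 1000))
        traces[3] = 0.0
        s = _session_from_traces(traces, geometry.roi_ids)
        pairs = mx.pairwise_roi_correlation(s, geometry)
        bad = geometry.roi_ids[3]
        involved = pairs[(pairs.roi_a == bad) | (pairs.roi_b == bad)]
        assert involved["r"].isna().all()
        assert pairs["r"].isna().sum() == 11

    def test_reassembled_matrix_symmetric_unit_diagonal_psd(self, geometry,
                                                            rng):
        traces = rng.normal(size=(12, 4000)).cumsum(axis=1)
        s = _session_from_traces(traces, geometry.roi_ids)
        pairs = mx.pairwise_roi_correlation(s, geometry)
        ids = sorted(geometry.roi_ids)
        mat = mx.correlation_matrix(pairs, ids)
        np.testing.assert_allclose(mat, mat.T, atol=1e-12)
        np.testing.assert_allclose(np.diag(mat), 1.0)
        eigvals = np.linalg.eigvalsh(mat)
        assert eigvals.min() > -1e-8


class TestDensityMap:
    def _pairs(self, d, r):
        return pd.DataFrame({"mouse": "m", "session": "s",
                             "roi_a": "a", "roi_b": "b",
                             "r": r, "d_norm": d})

    def test_identical_pairs_concentrate_in_one_bin(self):
        n = 37
        dm = mx.correlation_distance_density(
            self._pairs([0.5] * n, [0.3] * n))
        assert dm.grid.max() == n
        assert dm.grid.sum() == n

    def test_mass_conserved_through_clipping_and_smoothing(self, rng):
        d = rng.uniform(-0.2, 2.5, size=500)  # deliberately out of range
        r = rng.uniform(-1.0, 1.2, size=500)
        dm = mx.correlation_distance_density(self._pairs(d, r))
        assert dm.grid.sum() == 500
        assert dm.smoothed.sum() == pytest.approx(500, abs=1e-6)

    def test_contour_level_is_half_smoothed_peak(self, rng):
        dm = mx.correlation_distance_density(
            self._pairs(rng.uniform(0, 1.6, 300),
                        rng.uniform(-0.25, 1, 300)))
        assert dm.contour_level == pytest.approx(0.5 * dm.smoothed.max())
        assert dm.peak_density == pytest.approx(dm.smoothed.max())

    def test_invariant_to_pair_ordering(self, rng):
        d = rng.uniform(0, 1.6, 200)
        r = rng.uniform(-0.25, 1, 200)
        a = mx.correlation_distance_density(self._pairs(d, r))
        perm = rng.permutation(200)
        b = mx.correlation_distance_density(self._pairs(d[perm], r[perm]))
        np.testing.assert_array_equal(a.grid, b.grid)

    def test_uniform_pairs_give_roughly_flat_field(self):
        rng = np.random.default_rng(42)
        n = 40000
        dm = mx.correlation_distance_density(
            self._pairs(rng.uniform(0, 1.6, n), rng.uniform(-0.25, 1, n)),
            sigma_bins=0.0)
        expected = n / 1600
        sd = np.sqrt(expected)
        # every bin within 5 sigma of the uniform expectation
        assert np.abs(dm.grid - expected).max() < 5 * sd


class TestDrugChange:
    def _pairs(self, rows):
        return pd.DataFrame(rows, columns=mx.PAIR_COLUMNS)

    def _row(self, mouse, a, b, r, d):
        return {"mouse": mouse, "session": "s", "roi_a": a, "roi_b": b,
                "r": r, "d_norm": d}

    def test_no_change_gives_all_zero(self):
        rows = [self._row("m", "a", "b", 0.5, 0.4),
                self._row("m", "a", "c", 0.2, 1.2)]
        res = mx.drug_change(self._pairs(rows), self._pairs(rows))
        np.testing.assert_allclose(res.table["change"], 0.0)

    def test_halved_longrange_correlation_gives_minus_half(self):
        before = [self._row("m", "a", "b", 0.5, 1.2),
                  self._row("m", "c", "d", 0.5, 1.0)]
        after = [self._row("m", "a", "b", 0.25, 1.2),
                 self._row("m", "c", "d", 0.25, 1.0)]
        res = mx.drug_change(self._pairs(before), self._pairs(after))
        assert res.summary.set_index("range").loc["long", "median"] == \
            pytest.approx(-0.5)

    def test_boundary_pair_is_long_range(self):
        rows_b = [self._row("m", "a", "b", 0.5, 0.9)]
        rows_a = [self._row("m", "a", "b", 0.4, 0.9)]
        res = mx.drug_change(self._pairs(rows_b), self._pairs(rows_a),
                             cutoff=0.9)
        assert (res.table["range"] == "long").all()

    def test_zero_before_correlation_dropped_with_count(self):
        rows_b = [self._row("m", "a", "b", 0.0, 0.5),
                  self._row("m", "a", "c", 0.5, 0.5)]
        rows_a = [self._row("m", "a", "b", 0.3, 0.5),
                  self._row("m", "a", "c", 0.4, 0.5)]
        res = mx.drug_change(self._pairs(rows_b), self._pairs(rows_a))
        assert res.n_dropped_zero_before == 1
        assert len(res.table) == 1

    def test_session_coefficients_averaged_before_change(self):
        rows_b = [self._row("m", "a", "b", 0.4, 0.5),
                  self._row("m", "a", "b", 0.6, 0.5)]  # mean 0.5
        rows_a = [self._row("m", "a", "b", 0.25, 0.5)]
        res = mx.drug_change(self._pairs(rows_b), self._pairs(rows_a))
        assert res.table.iloc[0]["change"] == pytest.approx(-0.5)
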