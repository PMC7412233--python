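"""Moving-average ectopic flagging against brute-force oracles and ground truth."""

import csv

import numpy as np
import pytest

from mousecg import (
    EctopicConfig,
    EctopicEvent,
    NoiseSpec,
    RRSeries,
    SimulationConfig,
    flag_ectopic,
    moving_average_rr,
    simulate_record,
)

from conftest import run_detection
from mousecg import rr_intervals


def series(values, rate=1000.0):
    values = np.asarray(values, dtype=float)
    anchors = np.round(np.cumsum(values) * rate / 1000.0).astype(np.int64)
    return RRSeries(intervals_ms=values, anchor_indices=anchors, sample_rate=rate)


def brute_force_ma(values, window):
    """Direct O(n·w) recomputation of the centred, self-excluding mean."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    half = window // 2
    out = np.empty(n)
    for i in range(n):
        neighbors = [
            values[j]
            for j in range(max(0, i - half), min(n, i + half + 1))
            if j != i
        ]
        out[i] = np.mean(neighbors)
    return out


class TestMovingAverage:
    def test_constant_series_identity(self):
        ma = moving_average_rr(series([100.0] * 200), window=100)
        assert np.allclose(ma, 100.0)

    def test_excludes_centre_value(self):
        values = [100.0] * 50 + [60.0] + [100.0] * 50
        ma = moving_average_rr(series(values), window=100)
        assert ma[50] == pytest.approx(100.0)

    @pytest.mark.parametrize("window", [2, 5, 10, 100])
    @pytest.mark.parametrize("n", [2, 7, 150, 500])
    def test_matches_brute_force(self, window, n):
        rng = np.random.default_rng(window * 1000 + n)
        values = rng.uniform(60, 160, n)
        ma = moving_average_rr(series(values), window=window)
        assert np.allclose(ma, brute_force_ma(values, window))

    def test_too_short_series_rejected(self):
        with pytest.raises(ValueError):
            moving_average_rr(series([100.0]))


class TestFlagging:
    def test_forty_percent_deviation_flagged(self):
        values = [100.0] * 60 + [60.0] + [100.0] * 60
        rois = flag_ectopic(series(values))
        assert len(rois) == 1
        assert rois[0].deviation_fraction == pytest.approx(0.4)
        assert rois[0].interval_ms == pytest.approx(60.0)

    def test_below_threshold_not_flagged(self):
        values = [100.0] * 60 + [75.0] + [100.0] * 60
        assert flag_ectopic(series(values)) == []

    def test_constant_series_never_flagged_near_unity_threshold(self):
        rng = np.random.default_rng(0)
        values = 100.0 + rng.normal(0, 1, 300)
        cfg = EctopicConfig(deviation_threshold=0.999)
        assert flag_ectopic(series(values), cfg) == []

    def test_premature_plus_pause_merge_into_one_roi(self):
        values = [100.0] * 60 + [60.0, 140.0] + [100.0] * 60
        rois = flag_ectopic(series(values))
        assert len(rois) == 1
        # anchored on the most deviant interval of the run: the pause, whose
        # local reference (which still contains the 60 ms interval) is lower
        assert rois[0].interval_ms == pytest.approx(140.0, abs=1.0)
        # review window still spans the premature beat
        anchors = series(values).anchor_indices
        assert rois[0].window_start_s * 1000 <= anchors[60] <= rois[0].window_end_s * 1000

    def test_flags_invariant_under_time_shift(self):
        rng = np.random.default_rng(4)
        values = rng.uniform(90, 110, 300)
        values[120] = 55.0
        a = series(values)
        shifted = RRSeries(
            intervals_ms=values,
            anchor_indices=a.anchor_indices + 500_000,
            sample_rate=a.sample_rate,
        )
        ra = flag_ectopic(a)
        rb = flag_ectopic(shifted)
        assert [r.interval_ms for r in ra] == [r.interval_ms for r in rb]
        assert [r.beat_index + 500_000 for r in ra] == [r.beat_index for r in rb]

    def test_flags_match_brute_force(self):
        rng = np.random.default_rng(8)
        values = rng.uniform(70, 140, 400)
        cfg = EctopicConfig()
        ma = brute_force_ma(values, cfg.window_intervals)
        expect = np.nonzero(np.abs(values - ma) / ma > cfg.deviation_threshold)[0]
        got = flag_ectopic(series(values), cfg)
        # every brute-force deviant interval is inside some exported run
        anchors = series(values).anchor_indices
        covered = {int(anchors[i]) for i in expect}
        roi_spans = [
            (r.window_start_s * 1000, r.window_end_s * 1000) for r in got
        ]
        for a in covered:
            t = a  # anchor in ms at 1000 Hz
            assert any(lo <= t <= hi for lo, hi in roi_spans)


class TestEndToEnd:
    def test_injected_premature_beats_flagged(self):
        events = [EctopicEvent("premature", t, 0.6) for t in (30.0, 60.0, 90.0)]
        cfg = SimulationConfig(
            duration_s=120, sample_rate=2000, rr_sd_ms=3,
            ectopic_events=events, seed=33,
        )
        record, truth = simulate_record(cfg)
        _, _, annotations = run_detection(record)
        rois = flag_ectopic(rr_intervals(annotations))
        true_times = truth.true_peak_indices[truth.ectopic_flags] / 2000.0
        assert len(rois) == len(events)
        for t in true_times:
            assert any(abs(r.beat_index / 1000.0 - t) < 0.15 for r in rois)


class TestExport:
    def _setup(self, n_events):
        from mousecg import export_rois

        events = [
            EctopicEvent("premature", 10.0 * (k + 1), 0.6) for k in range(n_events)
        ]
        cfg = SimulationConfig(
            duration_s=40 if n_events else 20, sample_rate=2000, rr_sd_ms=3,
            ectopic_events=events, seed=44,
        )
        record, truth = simulate_record(cfg)
        bandpassed, _, annotations = run_detection(record)
        rois = flag_ectopic(rr_intervals(annotations))
        return export_rois, bandpassed, rois, annotations

    def test_three_rois_three_rows_three_pages(self, tmp_path):
        export_rois, bandpassed, rois, annotations = self._setup(3)
        assert len(rois) == 3
        written = export_rois(bandpassed, rois, annotations, tmp_path)
        with open(written["csv"]) as fh:
            rows = list(csv.reader(fh))
        assert len(rows) == 4  # header + 3
        assert written["pdf"].exists()

    def test_zero_rois_header_only_no_plot(self, tmp_path):
        export_rois, bandpassed, rois, annotations = self._setup(0)
        assert rois == []
        written = export_rois(bandpassed, [], annotations, tmp_path)
        with open(written["csv"]) as fh:
            rows = list(csv.reader(fh))
        assert len(rows) == 1
        assert "pdf" not in written

    def test_window_clipped_at_record_bounds(self, tmp_path):
        export_rois, bandpassed, rois, annotations = self._setup(3)
        early = rois[0]
        early.window_start_s = -1.0
        written = export_rois(bandpassed, rois, annotations, tmp_path)
        assert written["pdf"].exists()
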