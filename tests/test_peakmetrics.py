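import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from embryocal.detrend import detrend_trace
from embryocal.peakdetect import oracle_detect
from embryocal.peakmetrics import (
    PeakEvent,
    cell_summary_table,
    peak_events,
    percent,
    summarize_cell,
    summarize_tissue,
)
from embryocal.synthdata import SimConfig, calibrate_kernel, simulate_single_event_traces
from embryocal.traceio import traces_to_wide


class TestPeakEvents:
    def test_half_height_rule_worked_example(self):
        # 5-s frames, peak height 10 -> half 5: start at 5 s, end at 25 s
        trace = np.array([0, 2, 6, 10, 7, 4, 1], dtype=float)
        ev = peak_events(trace, [3], frame_interval_s=5.0)[0]
        assert ev.start_time_s == 5.0
        assert ev.end_time_s == 25.0
        assert ev.duration_s == 20.0
        assert ev.peak_intensity == 10.0

    def test_symmetric_triangle_has_symmetric_crossings(self):
        trace = np.array([0, 2, 4, 6, 8, 10, 8, 6, 4, 2, 0], dtype=float)
        ev = peak_events(trace, [5], frame_interval_s=1.0)[0]
        assert ev.peak_time_s - ev.start_time_s == ev.end_time_s - ev.peak_time_s

    def test_boundary_peak_flagged_truncated(self):
        trace = np.array([10.0, 4, 1, 0, 0, 0, 0], dtype=float)
        ev = peak_events(trace, [0], frame_interval_s=5.0)[0]
        assert ev.truncated
        assert ev.duration_s is None

    def test_duration_within_discretization_bound_of_fwhm(self):
        # noiseless kernels: FWHM <= duration <= FWHM + 2 frame intervals
        for fwhm in (15.0, 20.0, 30.0):
            k = calibrate_kernel(100.0, fwhm, 5.0)
            for phase in np.linspace(0, 5, 7):
                t = np.arange(121) * 5.0
                trace = k(t - 300.0 - phase)
                p = int(np.argmax(trace))
                ev = peak_events(trace, [p], frame_interval_s=5.0)[0]
                assert fwhm <= ev.duration_s <= fwhm + 10.0

    def test_out_of_range_peak_rejected(self):
        with pytest.raises(ValueError):
            peak_events(np.zeros(10), [10])


class TestSummarizeCell:
    def _events(self, times):
        return [
            PeakEvent(
                peak_frame=int(t // 5),
                peak_time_s=float(t),
                peak_intensity=1.0,
                start_time_s=None,
                end_time_s=None,
                truncated=True,
            )
            for t in times
        ]

    def test_mean_period_from_peak_times(self):
        s = summarize_cell(self._events([60.0, 240.0, 420.0]))
        assert s.mean_period_s == pytest.approx(180.0)

    def test_single_peak_has_no_period(self):
        s = summarize_cell(self._events([60.0]))
        assert np.isnan(s.mean_period_s)

    def test_empty_cell(self):
        s = summarize_cell([])
        assert s.n_peaks == 0 and np.isnan(s.mean_period_s)

    @settings(deadline=None, max_examples=25)
    @given(shift=st.floats(0, 1e5))
    def test_period_invariant_to_time_shift(self, shift):
        times = [100.0, 250.0, 475.0]
        a = summarize_cell(self._events(times)).mean_period_s
        b = summarize_cell(self._events([t + shift for t in times])).mean_period_s
        assert a == pytest.approx(b, rel=1e-9)

    def test_period_recovery_with_jitter(self, rng):
        # 1,000 cells, truth period 180 s with 20-s jitter
        periods = []
        for _ in range(1000):
            times = np.cumsum([60.0] + [180.0] * 3) + rng.normal(0, 20, size=4)
            s = summarize_cell(self._events(np.sort(times)))
            periods.append(s.mean_period_s)
        assert np.mean(periods) == pytest.approx(180.0, rel=0.05)


class TestSummarizeTissue:
    def _cells(self, n_by_tissue, active_by_tissue):
        rows = []
        cid = 0
        for tissue, n in n_by_tissue.items():
            for i in range(n):
                rows.append(
                    {
                        "embryo_id": "e0",
                        "cell_id": cid,
                        "tissue": tissue,
                        "n_peaks": 2 if i < active_by_tissue.get(tissue, 0) else 0,
                        "mean_peak_intensity": 1.0,
                        "mean_period_s": np.nan,
                        "mean_duration_s": np.nan,
                    }
                )
                cid += 1
        return pd.DataFrame(rows)

    def test_quiescent_dataset_gives_zero_percent_active(self):
        cells = self._cells({"epiblast": 5, "ExE": 3}, {})
        out = summarize_tissue(cells)
        assert (out["percent_active"] == 0.0).all()

    def test_reference_counts_and_conservation(self):
        counts = {"epiblast": 323, "ExE": 430, "emVE": 205, "exVE": 168}
        cells = self._cells(counts, {"epiblast": 32, "ExE": 163})
        out = summarize_tissue(cells).set_index("tissue")
        assert out["n_cells"].to_dict() == counts
        assert out["n_cells"].sum() == 1126
        assert out["n_active"].sum() <= out["n_cells"].sum()

    def test_active_fraction_matches_poisson_law(self):
        # exVE rate 0.82 over 10 min: P(>=1 event) = 1 - exp(-0.82)
        rate, n_cells = 0.82, 10000
        rng = np.random.default_rng(5)
        n_peaks = rng.poisson(rate, size=n_cells)
        cells = pd.DataFrame(
            {
                "embryo_id": "e0",
                "cell_id": np.arange(n_cells),
                "tissue": "exVE",
                "n_peaks": n_peaks,
                "mean_peak_intensity": 1.0,
                "mean_period_s": np.nan,
                "mean_duration_s": np.nan,
            }
        )
        out = summarize_tissue(cells)
        expected = 100.0 * (1.0 - np.exp(-rate))
        assert abs(out["percent_active"].iloc[0] - expected) < 2.0

    def test_unknown_tissue_rejected(self):
        cells = self._cells({"epiblast": 2}, {})
        cells.loc[0, "tissue"] = "notochord"
        with pytest.raises(ValueError):
            summarize_tissue(cells)


class TestPercent:
    @pytest.mark.parametrize(
        "k, n, expected",
        [(32, 323, 9.9), (2, 26, 7.7), (0, 5, 0.0), (20, 28, 71.4), (163, 430, 37.9)],
    )
    def test_printed_rates(self, k, n, expected):
        assert percent(k, n) == pytest.approx(expected, abs=0.05)

    def test_zero_denominator_rejected(self):
        with pytest.raises(ValueError):
            percent(0, 0)

    def test_k_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            percent(6, 5)


class TestEndToEndDuration:
    def test_mean_recovered_duration_near_kernel_fwhm(self):
        # small-scale version of the duration-recovery benchmark
        cfg = SimConfig(seed=17)
        traces, truth = simulate_single_event_traces(60, cfg)
        _, mat = traces_to_wide(traces)
        durations = []
        for i, row in enumerate(mat):
            det = detrend_trace(row)
            calls = [c.frame for c in oracle_detect(det)]
            for ev in peak_events(det, calls, frame_interval_s=5.0):
                if ev.duration_s is not None:
                    durations.append(ev.duration_s)
        assert 15.0 <= np.mean(durations) <= 25.0
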