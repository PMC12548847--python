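import numpy as np
import pandas as pd
import pytest

from embryocal.synthdata import (
    ConfigurationError,
    EmbryoLayout,
    LayoutError,
    SimConfig,
    calibrate_kernel,
    make_cohort_layouts,
    make_embryo_layout,
    simulate_embryo_dataset,
    simulate_inhibitor_experiment,
    simulate_single_event_traces,
    simulate_wave_movie,
)
from embryocal.traceio import traces_to_wide


class TestSimConfig:
    def test_frame_count_includes_t0(self):
        assert SimConfig(frame_interval_s=5, duration_s=600).n_frames == 121

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"frame_interval_s": 0},
            {"duration_s": -600},
            {"duration_s": 601},
            {"kernel_fwhm_s": 2.0},
            {"noise_sd": -1},
            {"tissue_rates": {"emVE": -0.1}},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ConfigurationError):
            SimConfig(**kwargs)


class TestKernel:
    @pytest.mark.parametrize("fwhm", [10.0, 20.0, 40.0])
    def test_fwhm_calibration(self, fwhm):
        k = calibrate_kernel(100.0, fwhm, 5.0)
        assert k.fwhm_s() == pytest.approx(fwhm, abs=1e-2)

    def test_peak_amplitude_normalized(self, kernel):
        t = np.linspace(0, 200, 20001)
        assert kernel(t).max() == pytest.approx(100.0, rel=1e-6)

    def test_zero_before_onset(self, kernel):
        assert np.all(kernel(np.array([-10.0, -0.1])) == 0.0)


class TestEmbryoLayout:
    def test_asymmetric_adjacency_rejected(self):
        with pytest.raises(LayoutError):
            EmbryoLayout(
                centroids_um={1: (0, 0), 2: (5, 5)},
                tissue={1: "emVE", 2: "emVE"},
                adjacency={1: frozenset({2}), 2: frozenset()},
            )

    def test_unknown_tissue_rejected(self):
        with pytest.raises(LayoutError):
            EmbryoLayout(centroids_um={1: (0, 0)}, tissue={1: "mesoderm"})

    def test_cohort_layouts_preserve_reference_tissue_totals(self):
        layouts = make_cohort_layouts(14)
        totals: dict = {}
        for lay in layouts:
            for t in lay.tissue.values():
                totals[t] = totals.get(t, 0) + 1
        assert totals == {"epiblast": 323, "ExE": 430, "emVE": 205, "exVE": 168}


class TestSimulateEmbryoDataset:
    def test_trace_length_and_one_trace_per_cell(self, small_layout):
        df, _ = simulate_embryo_dataset(SimConfig(seed=1), small_layout)
        sizes = df.groupby("cell_id")["frame"].size()
        assert (sizes == 121).all()
        assert len(sizes) == len(small_layout.cell_ids)

    def test_silent_configuration_gives_flat_traces(self, small_layout):
        cfg = SimConfig(
            tissue_rates={t: 0.0 for t in ("epiblast", "ExE", "emVE", "exVE")},
            noise_sd=0.0,
            drift_amplitude=0.0,
            seed=2,
        )
        df, truth = simulate_embryo_dataset(cfg, small_layout)
        assert len(truth.events) == 0
        assert np.allclose(df["intensity"], cfg.baseline_level)

    def test_reproducible_under_identical_seed(self, small_layout):
        a, ta = simulate_embryo_dataset(SimConfig(seed=7), small_layout)
        b, tb = simulate_embryo_dataset(SimConfig(seed=7), small_layout)
        pd.testing.assert_frame_equal(a, b)
        assert [e.onset_s for e in ta.events] == [e.onset_s for e in tb.events]

    def test_event_rate_matches_poisson_mean(self):
        # 1,000 epiblast cells x 200 replicate seeds at rate 0.15
        rate, n_cells, n_rep = 0.15, 1000, 200
        layout = make_embryo_layout({"epiblast": n_cells}, seed=0)
        counts = []
        for rep in range(n_rep):
            cfg = SimConfig(
                tissue_rates={"epiblast": rate, "ExE": 0, "emVE": 0, "exVE": 0},
                noise_sd=0.0,
                drift_amplitude=0.0,
                seed=rep,
            )
            _, truth = simulate_embryo_dataset(cfg, layout)
            counts.append(len(truth.events) / n_cells)
        mean = np.mean(counts)
        se = np.sqrt(rate / (n_cells * n_rep))  # Poisson variance = mean
        assert abs(mean - rate) < 3 * se

    def test_event_times_lie_under_local_maxima_of_noiseless_trace(self):
        cfg = SimConfig(noise_sd=0.0, drift_amplitude=0.0, seed=3)
        traces, truth = simulate_single_event_traces(50, cfg)
        _, mat = traces_to_wide(traces)
        for ev in truth.events:
            trace = mat[ev.cell_id]
            p = ev.peak_frame
            # sampled argmax sits within one frame of the recorded peak
            # (the continuous peak may fall between two frames)
            lo = max(p - 3, 0)
            assert abs(lo + int(np.argmax(trace[lo : p + 4])) - p) <= 1

    def test_unknown_tissue_rate_raises(self, small_layout):
        cfg = SimConfig(tissue_rates={"epiblast": 0.1}, seed=0)
        with pytest.raises(LayoutError):
            simulate_embryo_dataset(cfg, small_layout)


class TestWaveMovie:
    def test_front_advances_one_pixel_per_frame(self):
        # speed = pixel/frame: 1 um/s at 0.5-um pixels, 0.5-s frames
        movie, _ = simulate_wave_movie(
            speed_um_s=1.0,
            frame_interval_s=0.5,
            pixel_size_um=0.5,
            noise_sd=0.0,
            edge_width_um=0.05,
            n_frames=10,
        )
        fronts = [int((movie[t, :, 0] > 500).sum()) for t in range(10)]
        steps = np.diff(fronts)
        assert np.all(steps == 1)

    def test_intracellular_crossing_time(self):
        # 40-um-deep cell at 15.41 um/s: fully on after ceil(40/15.41/0.5) frames
        speed, depth, dt = 15.41, 40.0, 0.5
        movie, _ = simulate_wave_movie(
            cell_extent_um=(5.0, 45.0),
            speed_um_s=speed,
            frame_interval_s=dt,
            noise_sd=0.0,
            edge_width_um=0.05,
            n_frames=13,
        )
        expected = int(np.ceil(depth / speed / dt))
        inside = slice(11, 89)  # rows strictly inside the cell
        full = [np.all(movie[t, inside, 0] > 500) for t in range(13)]
        assert full.index(True) == expected

    def test_zero_speed_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_wave_movie(speed_um_s=0.0)

    def test_subpixel_front_warns(self):
        with pytest.warns(UserWarning, match="sub-pixel"):
            simulate_wave_movie(
                speed_um_s=0.5, frame_interval_s=0.5, pixel_size_um=0.5, n_frames=3
            )


class TestInhibitorExperiment:
    def test_identity_multiplier_matches_baseline_mean(self):
        rec = simulate_inhibitor_experiment(
            2000, baseline_rate=10.0, effect_multiplier=1.0, seed=0
        )
        means = rec.groupby("timepoint")["total_transients"].mean()
        assert means["treated_30min"] == pytest.approx(means["baseline"], rel=0.1)

    def test_zero_multiplier_abolishes_counts(self):
        rec = simulate_inhibitor_experiment(
            50, baseline_rate=18.0, effect_multiplier=0.0, seed=1
        )
        treated = rec[rec["timepoint"] == "treated_30min"]
        assert (treated["total_transients"] == 0).all()

    def test_treated_mean_recovers_calibrated_value(self):
        # baseline 18 with multiplier 1.3/18 -> treated mean 1.3
        rec = simulate_inhibitor_experiment(
            500, baseline_rate=18.0, effect_multiplier=1.3 / 18.0, seed=2
        )
        treated = rec[rec["timepoint"] == "treated_30min"]["total_transients"]
        se = treated.std(ddof=1) / np.sqrt(len(treated))
        assert abs(treated.mean() - 1.3) < 3 * se

    def test_empty_timepoints_rejected(self):
        with pytest.raises(ConfigurationError):
            simulate_inhibitor_experiment(
                5, baseline_rate=1.0, effect_multiplier=1.0, timepoints=()
            )
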