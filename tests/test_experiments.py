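import numpy as np
import pandas as pd
import pytest
from scipy.stats import studentized_range

from embryocal.experiments import (
    ScoringError,
    compare_groups,
    count_transients_per_embryo,
    score_migration,
    summarize_rates,
)
from embryocal.synthdata import (
    SimConfig,
    calibrate_kernel,
    make_embryo_layout,
    simulate_embryo_dataset,
    simulate_inhibitor_experiment,
)


def _short_timelapse(rate=0.0, seed=0, n_cells=6, noise_sd=0.0):
    # 2-min, 10-s-interval inhibitor-imaging configuration (13 frames)
    cfg = SimConfig(
        frame_interval_s=10.0,
        duration_s=120.0,
        tissue_rates={t: rate for t in ("epiblast", "ExE", "emVE", "exVE")},
        kernel_fwhm_s=20.0,
        drift_amplitude=0.0,
        noise_sd=noise_sd,
        seed=seed,
    )
    layout = make_embryo_layout({"emVE": n_cells}, seed=seed)
    return simulate_embryo_dataset(cfg, layout)


class TestCountTransients:
    def test_quiescent_embryo_counts_zero(self):
        traces, _ = _short_timelapse(rate=0.0, seed=1)
        assert count_transients_per_embryo(traces, frame_interval_s=10.0) == 0

    def test_single_injected_transient_counts_one(self):
        traces, _ = _short_timelapse(rate=0.0, seed=2)
        kernel = calibrate_kernel(100.0, 20.0, 5.0)
        t = np.arange(13) * 10.0
        first = traces["cell_id"] == traces["cell_id"].iloc[0]
        traces.loc[first, "intensity"] = (
            traces.loc[first, "intensity"].to_numpy() + kernel(t - 50.0)
        )
        assert count_transients_per_embryo(traces, frame_interval_s=10.0) == 1

    def test_poisson_mean_recovered_over_embryos(self):
        # counts drawn at baseline mean 18: sample mean within 3 SE
        records = simulate_inhibitor_experiment(
            500, baseline_rate=18.0, effect_multiplier=1.0, seed=4
        )
        base = records[records["timepoint"] == "baseline"]["total_transients"]
        se = base.std(ddof=1) / np.sqrt(len(base))
        assert abs(base.mean() - 18.0) < 3 * se


class TestCompareGroups:
    def test_identical_groups_give_f_zero_p_one(self):
        res = compare_groups({"a": [1, 2, 3], "b": [1, 2, 3], "c": [1, 2, 3]})
        assert res.f_statistic == 0.0
        assert res.p_value == 1.0

    def test_type_one_error_calibrated(self):
        """Two groups from the same normal: ANOVA rejects at alpha=0.05
        in 5% +- 1.5% of 1,000 replications."""
        from embryocal.benchmarks import anova_type1_error

        res = anova_type1_error(seed=7, n_rep=1000)
        assert abs(res["type1_rate"] - 0.05) <= 0.015

    def test_tukey_matches_studentized_range_brute_force(self):
        """Adjusted p-values against a direct studentized-range
        evaluation on a 3-group toy set."""
        groups = {
            "a": np.array([1.0, 2.0, 3.0, 2.0]),
            "b": np.array([5.0, 6.0, 7.0, 6.0]),
            "c": np.array([1.5, 2.5, 3.5, 2.0]),
        }
        res = compare_groups(groups)
        arrays = list(groups.values())
        k = len(arrays)
        n_total = sum(len(a) for a in arrays)
        df = n_total - k
        mse = sum(((a - a.mean()) ** 2).sum() for a in arrays) / df
        names = list(groups)
        expected = {}
        for i in range(k):
            for j in range(i + 1, k):
                a, b = arrays[i], arrays[j]
                se = np.sqrt(mse / 2 * (1 / len(a) + 1 / len(b)))
                q = abs(a.mean() - b.mean()) / se
                expected[(names[i], names[j])] = studentized_range.sf(q, k, df)
        for _, row in res.pairwise.iterrows():
            key = (row["group1"], row["group2"])
            assert float(row["p_adj"]) == pytest.approx(expected[key], abs=1e-4)

    def test_degenerate_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1.0, 1.0], "b": [2.0, 2.0]})

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            compare_groups({"a": [1, 2, 3]})

    def test_treated_group_flagged_in_inhibitor_design(self):
        records = pd.concat(
            [
                simulate_inhibitor_experiment(
                    12, 18.0, 1.3 / 18.0, condition="thapsigargin_10nM", seed=0
                ),
                simulate_inhibitor_experiment(
                    12, 17.0, 12.0 / 17.0, condition="DMSO", seed=1
                ),
            ]
        )
        treated = records[records["timepoint"] == "treated_30min"]
        groups = {
            c: g["total_transients"].to_numpy(float)
            for c, g in treated.groupby("condition")
        }
        res = compare_groups(groups)
        assert res.p_value < 0.05
        flagged = res.pairwise[res.pairwise["reject"] == True]  # noqa: E712
        assert len(flagged) == 1


class TestScoreMigration:
    def test_stationary_centroid_at_pole_not_migrated(self):
        track = np.array([[0.0, -10.0], [0.0, -10.0]])
        out = score_migration(track, embryo_center=np.array([0.0, 0.0]))
        assert not out.migrated
        assert out.angular_displacement_deg == pytest.approx(0.0)

    def test_45_degree_displacement_migrates(self):
        track = np.array([[0.0, -10.0], [7.07, -7.07]])
        out = score_migration(track, embryo_center=np.array([0.0, 0.0]))
        assert out.migrated
        assert out.angular_displacement_deg == pytest.approx(45.0, abs=0.1)

    def test_threshold_boundary_counts_as_migrated(self):
        angle = np.radians(30.0)
        track = np.array([[0.0, -1.0], [np.sin(angle) * 10, -np.cos(angle) * 10]])
        out = score_migration(track, embryo_center=np.zeros(2))
        assert out.migrated  # >= convention at exactly 30 degrees

    def test_short_track_rejected(self):
        with pytest.raises(ScoringError):
            score_migration(np.array([[0.0, -1.0]]), np.zeros(2))


class TestSummarizeRates:
    def test_migration_percentages_match_published_counts(self):
        outcomes = pd.DataFrame(
            {
                "embryo_id": [f"e{i}" for i in range(68)],
                "condition": ["DMSO"] * 28 + ["thapsigargin_10nM"] * 40,
                "migrated": [True] * 20 + [False] * 8 + [True] * 4 + [False] * 36,
            }
        )
        out = summarize_rates(outcomes=outcomes)["migration"].set_index("condition")
        assert out.loc["DMSO", "percent_migrated"] == pytest.approx(71.4, abs=0.05)
        assert out.loc["thapsigargin_10nM", "percent_migrated"] == pytest.approx(
            10.0, abs=0.05
        )

    def test_paired_deltas_keep_embryo_structure(self):
        records = simulate_inhibitor_experiment(
            8, 18.0, 0.1, seed=3
        )
        out = summarize_rates(records=records)
        deltas = out["paired_deltas"]
        assert len(deltas) == 8
        assert "treated_30min" in deltas.columns

    def test_effect_multiplier_recovered_at_scale(self):
        m = 1.3 / 18.0
        records = simulate_inhibitor_experiment(500, 18.0, m, seed=9)
        out = summarize_rates(records=records)["counts"].set_index("timepoint")
        ratio = (
            out.loc["treated_30min", "mean_transients"]
            / out.loc["baseline", "mean_transients"]
        )
        # 3-SE band for the ratio, delta method at n=500
        assert abs(ratio - m) < 3 * 0.012
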