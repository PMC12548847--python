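"""Parameter-recovery benchmarks run end-to-end on synthetic data.

Each function generates data with the synthetic-data module at the
package's study conditions, runs the relevant analysis stages, and
returns the recovered quantity together with the problem size.  They
are used both by the test suite and by the reproduction script.
"""

from __future__ import annotations

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .clustering import TraceClusterer
from .detrend import BaselineParams, detrend_trace
from .flowmotion import wave_speed_from_movie
from .peakdetect import (
    CNNPeakDetector,
    event_f1,
    match_events,
    oracle_detect,
)
from .peakmetrics import peak_events
from .synthdata import (
    SimConfig,
    simulate_archetype_dataset,
    simulate_inhibitor_experiment,
    simulate_single_event_traces,
    simulate_wave_movie,
)
from .traceio import traces_to_wide


def duration_recovery(
    seed: int = 11, n_traces: int = 500, fwhm_s: float = 20.0
) -> dict:
    """Mean half-height transient duration recovered from synthetic
    traces (5-s frames, 10-min records, SNR 5, one isolated transient
    each) passed through de-trending, detection and the half-peak rule."""
    config = SimConfig(
        kernel_fwhm_s=fwhm_s, kernel_amplitude=100.0, noise_sd=20.0, seed=seed
    )
    traces, truth = simulate_single_event_traces(n_traces, config)
    _, mat = traces_to_wide(traces)
    params = BaselineParams()
    durations = []
    true_by_cell = truth.events_by_cell()
    for i, row in enumerate(mat):
        det = detrend_trace(row, params)
        calls = oracle_detect(det, frame_interval_s=config.frame_interval_s)
        truth_frames = [ev.peak_frame for ev in true_by_cell.get(i, [])]
        events = peak_events(
            det,
            [c.frame for c in calls],
            frame_interval_s=config.frame_interval_s,
        )
        for ev in events:
            matched = any(
                abs(ev.peak_frame - tf) <= 1 for tf in truth_frames
            )
            if matched and ev.duration_s is not None:
                durations.append(ev.duration_s)
    return {
        "mean_duration_s": float(np.mean(durations)),
        "n_events": len(durations),
        "n_traces": n_traces,
    }


def wave_speed_recovery(
    seed: int = 7, true_speed_um_s: float = 15.41
) -> dict:
    """Speed of a synthetic intracellular apical-to-basal wave recovered
    by binarization + sub-pixel front localization + regression
    (0.5-um pixels, 0.5-s frames, mild noise)."""
    movie, truth = simulate_wave_movie(
        speed_um_s=true_speed_um_s,
        frame_interval_s=0.5,
        pixel_size_um=0.5,
        noise_sd=20.0,
        seed=seed,
    )
    est = wave_speed_from_movie(
        movie, pixel_size_um=0.5, frame_interval_s=0.5, axis=1
    )
    return {
        "speed_um_s": est.speed_um_s,
        "true_speed_um_s": truth.wave_speed_um_s,
        "direction": est.direction,
        "n_frames": movie.shape[0],
    }


def cluster_recovery(seed: int = 0) -> dict:
    """Global-mode clustering of the 14-embryo archetype cohort
    (quiescent cells plus three oscillatory archetypes): number of
    recovered groups and adjusted Rand index against truth."""
    traces, truth = simulate_archetype_dataset(seed=seed)
    meta, mat = traces_to_wide(traces)
    params = BaselineParams()
    peak_counts = np.array(
        [len(oracle_detect(detrend_trace(row, params))) for row in mat]
    )
    model = TraceClusterer(min_cluster_size=20, min_samples=10, mode="global")
    labels = model.fit_predict(traces, peak_counts)
    truth_aligned = truth.loc[
        list(zip(model.meta_["embryo_id"], model.meta_["cell_id"]))
    ].to_numpy()
    return {
        "n_groups": int(np.unique(labels).size),
        "ari": float(adjusted_rand_score(truth_aligned, labels)),
        "n_cells": len(labels),
    }


def cluster_recovery_mean_ari(n_seeds: int = 10, seed: int = 0) -> dict:
    aris, groups = [], []
    for s in range(n_seeds):
        res = cluster_recovery(seed=seed + s)
        aris.append(res["ari"])
        groups.append(res["n_groups"])
    return {
        "mean_ari": float(np.mean(aris)),
        "n_groups_mode": int(np.bincount(groups).argmax()),
        "n_seeds": n_seeds,
    }


def snr_benchmark_dataset(
    n_cells: int,
    seed: int,
    amplitude: float = 100.0,
    noise_sd: float = 20.0,
    rate: float = 3.0,
) -> tuple[np.ndarray, list]:
    """De-trended synthetic traces with truth peak-frame labels for
    detector benchmarks.  Events are sampled with a refractory interval
    of one transient width (25 s): events closer than the detectors'
    minimum separation are indistinguishable by construction and are
    excluded from the benchmark by design."""
    from .synthdata import make_embryo_layout, simulate_embryo_dataset

    layout = make_embryo_layout(
        {"emVE": n_cells}, embryo_id=f"sim{seed}", seed=seed
    )
    cfg = SimConfig(
        kernel_amplitude=amplitude,
        noise_sd=noise_sd,
        tissue_rates={"epiblast": rate, "ExE": rate, "emVE": rate, "exVE": rate},
        seed=seed,
    )
    traces, truth = simulate_embryo_dataset(cfg, layout, min_event_separation_s=25.0)
    _, mat = traces_to_wide(traces)
    params = BaselineParams()
    det = np.vstack([detrend_trace(r, params) for r in mat])
    by_cell = truth.events_by_cell()
    labels = [
        np.array(sorted({ev.peak_frame for ev in by_cell.get(cid, [])}), dtype=int)
        for cid in sorted(layout.centroids_um)
    ]
    return det, labels


def detector_cross_validation(
    seed: int = 0,
    n_train: int = 60,
    n_test: int = 30,
    amplitude: float = 100.0,
    noise_sd: float = 20.0,
    rate: float = 3.0,
    epochs: int = 80,
    n_models: int = 3,
) -> dict:
    """Train the CNN on synthetic traces (truth-labeled) and compare its
    calls on held-out traces with the deterministic detector and with
    truth (event-level, one-frame matching tolerance)."""
    train_x, train_y = snr_benchmark_dataset(n_train, seed, amplitude, noise_sd, rate)
    test_x, test_y = snr_benchmark_dataset(
        n_test, seed + 1, amplitude, noise_sd, rate
    )
    model = CNNPeakDetector(
        epochs=epochs, n_models=n_models, random_state=seed
    ).fit(train_x, train_y)
    cnn_calls = model.predict(test_x)
    tp = fp = fn = 0
    otp = ofp = ofn = 0
    for trace, calls, truth_frames in zip(test_x, cnn_calls, test_y):
        t, p, n = match_events(calls, truth_frames)
        tp, fp, fn = tp + t, fp + p, fn + n
        oracle_frames = [c.frame for c in oracle_detect(trace)]
        t, p, n = match_events(calls, oracle_frames)
        otp, ofp, ofn = otp + t, ofp + p, ofn + n
    precision = tp / (tp + fp) if tp + fp else 1.0
    recall = tp / (tp + fn) if tp + fn else 1.0
    return {
        "precision": precision,
        "recall": recall,
        "f1_vs_truth": 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else 1.0,
        "f1_vs_oracle": (
            2 * otp / (2 * otp + ofp + ofn) if (2 * otp + ofp + ofn) else 1.0
        ),
        "n_test_traces": n_test,
        "model": model,
    }


def detector_oracle_equivalence(
    seed: int = 0,
    n_train: int = 60,
    n_test: int = 60,
    epochs: int = 80,
) -> dict:
    """Oracle-equivalence: train the CNN on the deterministic detector's
    calls (the stand-in for manual annotation) and measure event-level
    agreement between the two detectors on held-out traces."""
    train_x, _ = snr_benchmark_dataset(n_train, seed)
    test_x, test_truth = snr_benchmark_dataset(n_test, seed + 10)
    oracle_labels = [
        np.array([c.frame for c in oracle_detect(tr)], dtype=int) for tr in train_x
    ]
    model = CNNPeakDetector(epochs=epochs, random_state=seed).fit(
        train_x, oracle_labels
    )
    calls = model.predict(test_x)
    atp = afp = afn = 0
    for trace, c in zip(test_x, calls):
        o = [x.frame for x in oracle_detect(trace)]
        t, p, n = match_events(c, o)
        atp, afp, afn = atp + t, afp + p, afn + n
    return {
        "f1_vs_oracle": (
            2 * atp / (2 * atp + afp + afn) if (2 * atp + afp + afn) else 1.0
        ),
        "n_test_traces": n_test,
        "model": model,
    }


def inhibitor_recovery(
    seed: int = 0,
    n_embryos: int = 500,
    baseline_rate: float = 18.0,
    treated_mean: float = 1.3,
) -> dict:
    """Generator calibrated to the thapsigargin experiment (baseline mean
    18 transients per embryo, treated mean 1.3): recovered condition
    means and the standard errors of the estimates."""
    records = simulate_inhibitor_experiment(
        n_embryos=n_embryos,
        baseline_rate=baseline_rate,
        effect_multiplier=treated_mean / baseline_rate,
        timepoints=("baseline", "treated_30min"),
        seed=seed,
    )
    pivot = records.pivot(
        index="embryo_id", columns="timepoint", values="total_transients"
    )
    base = pivot["baseline"].to_numpy(dtype=float)
    treat = pivot["treated_30min"].to_numpy(dtype=float)
    return {
        "baseline_mean": float(base.mean()),
        "treated_mean": float(treat.mean()),
        "baseline_se": float(base.std(ddof=1) / np.sqrt(len(base))),
        "treated_se": float(treat.std(ddof=1) / np.sqrt(len(treat))),
        "n_embryos": n_embryos,
        "records": records,
    }


def anova_type1_error(
    seed: int = 0, n_rep: int = 1000, n_per_group: int = 12, alpha: float = 0.05
) -> dict:
    """Empirical type-I error of the one-way ANOVA on two groups drawn
    from the same normal distribution."""
    from scipy.stats import f_oneway

    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_rep):
        a = rng.normal(size=n_per_group)
        b = rng.normal(size=n_per_group)
        _, p = f_oneway(a, b)
        rejections += p < alpha
    return {"type1_rate": rejections / n_rep, "n_rep": n_rep}
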