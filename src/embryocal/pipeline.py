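"""End-to-end pipeline orchestration.

A single configuration dict drives the stages in dependency order:
simulate (or load) traces -> de-trend -> detect peaks -> per-cell /
per-tissue metrics -> dynamics clustering -> kymograph.  All randomness
flows from one seed, so a run is deterministic: identical configuration
and seed give byte-identical CSV outputs.  A provenance record (resolved
configuration, config hash, seed, package version, timestamp) is written
alongside the outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .clustering import TraceClusterer
from .detrend import BaselineParams, detrend_traces
from .kymograph import KymographSpec, render_kymograph, save_kymograph
from .peakdetect import oracle_detect
from .peakmetrics import metrics_from_calls
from .synthdata import SimConfig, make_cohort_layouts, simulate_embryo_dataset
from .traceio import read_traces, traces_to_wide, write_traces

logger = logging.getLogger(__name__)

DEFAULT_CONFIG: dict = {
    "seed": 0,
    "stages": {
        "simulate": True,
        "detrend": True,
        "detect": True,
        "metrics": True,
        "cluster": True,
        "kymograph": True,
    },
    "simulate": {"n_embryos": 3, "cells_per_embryo": 24},
    "detrend": {"lam": 1e5, "p": 0.01},
    "detect": {"z_thresh": 3.0, "min_separation": 3},
    "cluster": {"min_cluster_size": 20, "min_samples": 10, "mode": "global"},
    "kymograph": {"mode": "global_zscore"},
    "traces_path": None,
}


class PipelineError(RuntimeError):
    """Stage failure with stage context."""


def _merge(base: dict, override: dict) -> dict:
    out = dict(base)
    for k, v in override.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _merge(out[k], v)
        else:
            out[k] = v
    return out


def run_pipeline(config: dict | None = None, out_dir: str | Path = "run") -> Path:
    """Run enabled stages, writing CSV/PNG outputs and a provenance log."""
    cfg = _merge(DEFAULT_CONFIG, config or {})
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])
    stages = cfg["stages"]

    # -- input traces
    if stages.get("simulate"):
        sim = cfg["simulate"]
        n_embryos = int(sim["n_embryos"])
        per = int(sim["cells_per_embryo"])
        counts = {
            "epiblast": per // 4,
            "ExE": per // 4,
            "emVE": per // 4,
            "exVE": per - 3 * (per // 4),
        }
        totals = {t: n * n_embryos for t, n in counts.items()}
        layouts = make_cohort_layouts(n_embryos, totals, seed=seed)
        frames = []
        for i, layout in enumerate(layouts):
            sc = SimConfig(seed=seed + 1000 + i)
            df, _ = simulate_embryo_dataset(sc, layout)
            frames.append(df)
        traces = pd.concat(frames, ignore_index=True)
    elif cfg.get("traces_path"):
        traces = read_traces(cfg["traces_path"])
    else:
        raise PipelineError("input: no traces (enable simulate or set traces_path)")
    write_traces(traces, out / "traces.csv")

    # -- detrend
    if stages.get("detrend"):
        try:
            params = BaselineParams(**cfg["detrend"])
            detrended = detrend_traces(traces, params)
        except Exception as exc:  # noqa: BLE001
            raise PipelineError(f"detrend: {exc}") from exc
        write_traces(detrended, out / "detrended.csv")
    else:
        detrended = traces

    meta, mat = traces_to_wide(detrended)
    frame_interval = float(
        detrended["time_s"].iloc[1] - detrended["time_s"].iloc[0]
    )

    # -- detect
    peak_frames = None
    if stages.get("detect"):
        det_cfg = cfg["detect"]
        peak_frames = [
            np.array(
                [
                    c.frame
                    for c in oracle_detect(
                        row,
                        z_thresh=det_cfg.get("z_thresh", 3.0),
                        min_separation=det_cfg.get("min_separation", 3),
                        frame_interval_s=frame_interval,
                    )
                ],
                dtype=int,
            )
            for row in mat
        ]
        peaks_df = pd.concat(
            [
                pd.DataFrame(
                    {
                        "embryo_id": row["embryo_id"],
                        "cell_id": row["cell_id"],
                        "frame": frames_i,
                        "time_s": frames_i * frame_interval,
                    }
                )
                for (_, row), frames_i in zip(meta.iterrows(), peak_frames)
                if len(frames_i)
            ],
            ignore_index=True,
        ) if any(len(f) for f in peak_frames) else pd.DataFrame(
            columns=["embryo_id", "cell_id", "frame", "time_s"]
        )
        peaks_df.to_csv(out / "peaks.csv", index=False)

    # -- metrics
    if stages.get("metrics"):
        if peak_frames is None:
            raise PipelineError("metrics: requires the detect stage")
        cells, tissues = metrics_from_calls(
            mat, meta, peak_frames, frame_interval_s=frame_interval
        )
        cells.to_csv(out / "cells.csv", index=False, float_format="%.8g")
        tissues.to_csv(out / "tissues.csv", index=False, float_format="%.8g")

    # -- clustering
    labels = None
    if stages.get("cluster"):
        if peak_frames is None:
            raise PipelineError("cluster: requires the detect stage")
        cl = cfg["cluster"]
        model = TraceClusterer(
            min_cluster_size=int(cl["min_cluster_size"]),
            min_samples=int(cl["min_samples"]),
            mode=cl["mode"],
        )
        counts = np.array([len(f) for f in peak_frames])
        labels = model.fit_predict(detrended, counts)
        model.result_.table(model.meta_).to_csv(out / "labels.csv", index=False)

    # -- kymograph
    if stages.get("kymograph"):
        first_peak = np.array(
            [
                float(f[0]) * frame_interval if len(f) else np.nan
                for f in (peak_frames or [[]] * len(meta))
            ]
        )
        if labels is None:
            logger.info(
                "clustering disabled: kymograph rows fall back to tissue order"
            )
            tissue_order = {t: i for i, t in enumerate(meta["tissue"].unique())}
            labels_for_rows = meta["tissue"].map(tissue_order).to_numpy()
        else:
            labels_for_rows = labels
        spec = KymographSpec(mode=cfg["kymograph"]["mode"])
        image, matrix, _ = render_kymograph(
            detrended, labels_for_rows, first_peak, spec
        )
        save_kymograph(image, matrix, out / "kymograph.png", out / "kymograph.csv")

    provenance = {
        "config": cfg,
        "config_sha256": hashlib.sha256(
            json.dumps(cfg, sort_keys=True, default=str).encode()
        ).hexdigest(),
        "seed": seed,
        "package_version": __version__,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=1, default=str))
    return out
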