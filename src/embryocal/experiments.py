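"""Inhibitor-experiment quantification and group comparisons.

SERCA-inhibitor experiments (thapsigargin 10 nM, cyclopiazonic acid
200 nM, DMSO control) are scored as total transient counts per embryo
per timepoint (baseline / after 30 min treatment / after 30 min
recovery), from short 2-min timelapses at a 10-s interval.  Migration
experiments score whether the distal visceral endoderm (DVE) domain has
moved away from the distal pole of the egg cylinder, here by an angular
displacement threshold on the DVE-centroid track.  Group comparisons
are one-way ANOVA followed by all-pairs Tukey HSD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import f_oneway
from statsmodels.stats.multicomp import pairwise_tukeyhsd

from .peakdetect import oracle_detect
from .peakmetrics import percent
from .traceio import traces_to_wide

CONDITIONS = ("DMSO", "thapsigargin_10nM", "CPA_200nM")
TIMEPOINTS = ("baseline", "treated_30min", "recovery_30min")


class ScoringError(ValueError):
    """Migration track too short to score."""


# ---------------------------------------------------------------------------
# transient counting
# ---------------------------------------------------------------------------


def count_transients_per_embryo(
    traces: pd.DataFrame,
    detector=None,
    frame_interval_s: float = 10.0,
    **oracle_kwargs,
) -> int:
    """Total transient count: sum over cells of detected peaks.

    The deterministic detector is the default for these short (13-frame)
    records, where the CNN's 35-sample window would be dominated by edge
    padding; pass a fitted :class:`~embryocal.peakdetect.CNNPeakDetector`
    to override.
    """
    meta, mat = traces_to_wide(traces)
    if detector is not None and mat.shape[1] < detector.window:
        warnings.warn(
            "trace shorter than the detector window; using the "
            "deterministic detector instead",
            stacklevel=2,
        )
        detector = None
    total = 0
    if detector is None:
        for row in mat:
            total += len(
                oracle_detect(row, frame_interval_s=frame_interval_s, **oracle_kwargs)
            )
    else:
        for frames in detector.predict(mat):
            total += len(frames)
    return total


# ---------------------------------------------------------------------------
# group comparison
# ---------------------------------------------------------------------------


@dataclass
class ComparisonResult:
    f_statistic: float
    p_value: float
    group_means: dict
    pairwise: pd.DataFrame  # group1, group2, meandiff, p_adj, reject


def compare_groups(groups: dict, alpha: float = 0.05) -> ComparisonResult:
    """One-way ANOVA plus all-pairs Tukey HSD.

    ``groups`` maps group name -> 1D array of observations (>= 2 groups
    of >= 2 observations each).
    """
    names = list(groups)
    if len(names) < 2:
        raise ValueError("need at least 2 groups")
    arrays = [np.asarray(groups[g], dtype=float) for g in names]
    if any(a.size < 2 for a in arrays):
        raise ValueError("each group needs at least 2 observations")
    if all(np.var(a) == 0 for a in arrays):
        raise ValueError("zero within-group variance in every group")
    if len(set(map(len, arrays))) == 1 and all(
        np.array_equal(arrays[0], a) for a in arrays[1:]
    ):
        # identical groups: F = 0, p = 1 (scipy warns about this case)
        f_stat, p_val = 0.0, 1.0
    else:
        f_stat, p_val = f_oneway(*arrays)
    values = np.concatenate(arrays)
    labels = np.concatenate([[g] * len(a) for g, a in zip(names, arrays)])
    tukey = pairwise_tukeyhsd(values, labels, alpha=alpha)
    pairwise = pd.DataFrame(
        tukey.summary().data[1:], columns=tukey.summary().data[0]
    ).rename(columns={"p-adj": "p_adj"})
    return ComparisonResult(
        f_statistic=float(f_stat),
        p_value=float(p_val),
        group_means={g: float(np.mean(a)) for g, a in zip(names, arrays)},
        pairwise=pairwise,
    )


# ---------------------------------------------------------------------------
# migration scoring
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MigrationOutcome:
    embryo_id: str
    condition: str
    migrated: bool
    angular_displacement_deg: float


def score_migration(
    track: np.ndarray,
    embryo_center: np.ndarray,
    angle_threshold_deg: float = 30.0,
    embryo_id: str = "",
    condition: str = "DMSO",
) -> MigrationOutcome:
    """Migration call from the DVE-domain centroid track.

    The embryo is assumed oriented long-axis vertical, ExE up, so the
    distal pole direction is -y from the embryo center.  The outcome is
    the final angular displacement of the DVE centroid from the distal
    pole axis; displacement at or above the threshold counts as migrated
    (>= convention).
    """
    track = np.asarray(track, dtype=float)
    if track.ndim != 2 or track.shape[0] < 2:
        raise ScoringError("track needs at least 2 positions")
    center = np.asarray(embryo_center, dtype=float)
    final = track[-1] - center
    if np.linalg.norm(final) == 0:
        angle = 0.0
    else:
        distal = np.array([0.0, -1.0])
        cosang = float(final @ distal / np.linalg.norm(final))
        angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
    return MigrationOutcome(
        embryo_id=embryo_id,
        condition=condition,
        migrated=bool(angle >= angle_threshold_deg - 1e-9),
        angular_displacement_deg=angle,
    )


# ---------------------------------------------------------------------------
# summaries
# ---------------------------------------------------------------------------


def summarize_rates(
    outcomes: pd.DataFrame | None = None,
    records: pd.DataFrame | None = None,
) -> dict:
    """Condition-level summary tables.

    ``outcomes`` (embryo_id, condition, migrated) yields migration rates
    per condition via :func:`~embryocal.peakmetrics.percent`;
    ``records`` (embryo_id, condition, timepoint, total_transients)
    yields mean counts per condition x timepoint plus paired per-embryo
    deltas against baseline.
    """
    out: dict = {}
    if outcomes is not None and len(outcomes):
        rows = []
        for cond, grp in outcomes.groupby("condition", sort=False):
            n = len(grp)
            if n == 0:
                warnings.warn(f"no outcomes for condition {cond}", stacklevel=2)
                continue
            k = int(grp["migrated"].sum())
            rows.append(
                {
                    "condition": cond,
                    "n": n,
                    "k_migrated": k,
                    "percent_migrated": percent(k, n),
                }
            )
        out["migration"] = pd.DataFrame(rows)
    if records is not None and len(records):
        counts = (
            records.groupby(["condition", "timepoint"], sort=False)[
                "total_transients"
            ]
            .mean()
            .reset_index()
            .rename(columns={"total_transients": "mean_transients"})
        )
        out["counts"] = counts
        wide = records.pivot_table(
            index=["condition", "embryo_id"],
            columns="timepoint",
            values="total_transients",
        )
        if "baseline" in wide.columns:
            deltas = wide.subtract(wide["baseline"], axis=0).drop(
                columns="baseline"
            )
            out["paired_deltas"] = deltas.reset_index()
    return out
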