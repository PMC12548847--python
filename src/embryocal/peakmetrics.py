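"""Per-peak, per-cell and per-tissue transient metrics.

Peak duration follows the half-height rule at the acquisition sampling:
the start time is the last frame before the rising trace reaches half
the peak height, the end time the first frame after the falling trace
drops below it, and duration = end - start.  Half height is measured on
the de-trended scale; by default relative to zero (the de-trended
baseline), optionally relative to the median of the inter-peak interval.
Per-cell summaries are the mean peak count, mean peak intensity, the
oscillation period (mean peak-to-peak distance, undefined for cells with
fewer than two peaks) and mean duration; per-tissue summaries add the
active-cell percentage (cells with at least one transient).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthdata import TISSUES


@dataclass(frozen=True)
class PeakEvent:
    """One transient with half-height start/end times (seconds)."""

    peak_frame: int
    peak_time_s: float
    peak_intensity: float
    start_time_s: float | None
    end_time_s: float | None
    truncated: bool

    @property
    def duration_s(self) -> float | None:
        if self.truncated or self.start_time_s is None or self.end_time_s is None:
            return None
        return self.end_time_s - self.start_time_s


def peak_events(
    trace: np.ndarray,
    peak_frames,
    frame_interval_s: float = 5.0,
    baseline: str = "median",
) -> list[PeakEvent]:
    """Half-height start/end times for each detected peak.

    ``baseline`` is the reference level for "half peak intensity":
    ``median`` (default; median of the trace between the flanking peaks
    / trace ends, excluding the peak's immediate neighbourhood, which
    absorbs any residual offset the de-trender leaves in quiet stretches)
    or ``zero`` (the nominal de-trended baseline).  Half-crossings
    are searched only within the inter-peak interval; a peak whose
    half-crossing is cut off by the trace boundary or an unresolved
    neighbouring peak is flagged truncated and reports no duration.
    """
    x = np.asarray(trace, dtype=float)
    frames = np.sort(np.asarray(peak_frames, dtype=int))
    n = x.size
    if frames.size and (frames.min() < 0 or frames.max() >= n):
        raise ValueError("peak frame out of range")
    events = []
    for i, p in enumerate(frames):
        left_bound = int(frames[i - 1]) if i > 0 else 0
        right_bound = int(frames[i + 1]) if i + 1 < frames.size else n - 1
        if baseline == "median":
            # median of the inter-peak interval, excluding the immediate
            # neighbourhood of the peak so the transient itself does not
            # inflate its own reference level
            idx = np.r_[left_bound : max(p - 2, left_bound), p + 3 : right_bound + 1]
            segment = x[idx] if idx.size else x[left_bound : right_bound + 1]
            ref = float(np.median(segment))
        elif baseline == "zero":
            ref = 0.0
        else:
            raise ValueError(f"unknown baseline mode {baseline!r}")
        height = x[p] - ref
        half = ref + height / 2.0
        start = None
        for j in range(p - 1, left_bound - 1, -1):
            if x[j] < half:
                start = j
                break
        end = None
        for j in range(p + 1, right_bound + 1):
            if x[j] < half:
                end = j
                break
        truncated = start is None or end is None
        events.append(
            PeakEvent(
                peak_frame=int(p),
                peak_time_s=p * frame_interval_s,
                peak_intensity=float(x[p]),
                start_time_s=None if start is None else start * frame_interval_s,
                end_time_s=None if end is None else end * frame_interval_s,
                truncated=truncated,
            )
        )
    return events


@dataclass(frozen=True)
class CellSummary:
    """Per-cell transient metrics; period requires >= 2 peaks (else NaN,
    mirroring the N/A convention of tabulated per-cell outputs)."""

    embryo_id: str
    cell_id: int
    tissue: str
    n_peaks: int
    mean_peak_intensity: float
    mean_period_s: float
    mean_duration_s: float


def summarize_cell(
    events: list[PeakEvent],
    embryo_id: str = "",
    cell_id: int = 0,
    tissue: str = "emVE",
) -> CellSummary:
    """Aggregate a cell's peak events (sorted by peak time)."""
    n = len(events)
    times = np.array([e.peak_time_s for e in events])
    period = float(np.mean(np.diff(times))) if n >= 2 else float("nan")
    intensities = [e.peak_intensity for e in events]
    durations = [e.duration_s for e in events if e.duration_s is not None]
    return CellSummary(
        embryo_id=embryo_id,
        cell_id=cell_id,
        tissue=tissue,
        n_peaks=n,
        mean_peak_intensity=float(np.mean(intensities)) if intensities else 0.0,
        mean_period_s=period,
        mean_duration_s=float(np.mean(durations)) if durations else float("nan"),
    )


def cell_summary_table(summaries: list[CellSummary]) -> pd.DataFrame:
    return pd.DataFrame([s.__dict__ for s in summaries])


def summarize_tissue(cells: pd.DataFrame) -> pd.DataFrame:
    """Per-tissue aggregation of a cell-summary table.

    The emVE is treated as a single tissue (no DVE subdivision).  Returns
    one row per tissue present: n_cells, n_active, percent_active, mean
    peak count, mean period (over cells with a defined period), mean
    duration, mean peak intensity.
    """
    unknown = set(cells["tissue"]) - set(TISSUES)
    if unknown:
        raise ValueError(f"unknown tissue labels: {sorted(unknown)}")
    rows = []
    for tissue, grp in cells.groupby("tissue", sort=False):
        n_cells = len(grp)
        n_active = int((grp["n_peaks"] >= 1).sum())
        active = grp[grp["n_peaks"] >= 1]
        rows.append(
            {
                "tissue": tissue,
                "n_cells": n_cells,
                "n_active": n_active,
                "percent_active": percent(n_active, n_cells),
                "mean_n_peaks": float(grp["n_peaks"].mean()),
                "mean_period_s": float(grp["mean_period_s"].mean()),
                "mean_duration_s": float(active["mean_duration_s"].mean())
                if len(active)
                else float("nan"),
                "mean_peak_intensity": float(active["mean_peak_intensity"].mean())
                if len(active)
                else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def percent(k: int, n: int) -> float:
    """100*k/n at one-decimal precision; n must be positive, 0 <= k <= n."""
    if n <= 0:
        raise ValueError("percent undefined for n <= 0")
    if not 0 <= k <= n:
        raise ValueError("require 0 <= k <= n")
    return round(100.0 * k / n, 1)


def metrics_from_calls(
    traces_wide: np.ndarray,
    meta: pd.DataFrame,
    peak_frames_per_cell: list,
    frame_interval_s: float = 5.0,
    baseline: str = "median",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Cell- and tissue-summary tables from de-trended traces plus
    per-cell peak-frame calls (same row order as ``meta``)."""
    summaries = []
    for (_, row), trace, frames in zip(
        meta.iterrows(), traces_wide, peak_frames_per_cell
    ):
        events = peak_events(trace, frames, frame_interval_s, baseline)
        summaries.append(
            summarize_cell(
                events,
                embryo_id=row["embryo_id"],
                cell_id=row["cell_id"],
                tissue=row["tissue"],
            )
        )
    cells = cell_summary_table(summaries)
    return cells, summarize_tissue(cells)
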