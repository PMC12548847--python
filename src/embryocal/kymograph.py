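"""Kymograph rendering: cells as rows, time points as columns.

Each row is one cell's normalized intensity trace, coloured with the
"magma" colormap.  Per-embryo kymographs use embryo-wide min-max
normalization mapped onto [0, 1]; the global (cross-embryo) kymograph
uses per-embryo z-scores with the colormap applied to the positive
value range [0, 2] (negative z clips to 0, values above 2 clip to 2).
Rows are ordered by an indirect stable sort on (cluster id, time of
first peak); rows without peaks sort after peaked rows within their
cluster, keeping their input order.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from matplotlib import colormaps

from .clustering import normalize_traces


@dataclass(frozen=True)
class KymographSpec:
    mode: str = "per_embryo_minmax"  # or "global_zscore"
    cmap: str = "magma"

    @property
    def value_range(self) -> tuple[float, float]:
        return (0.0, 1.0) if self.mode == "per_embryo_minmax" else (0.0, 2.0)


def row_order(
    cluster_ids: np.ndarray, first_peak_times: np.ndarray
) -> np.ndarray:
    """Permutation ordering rows by (cluster, first-peak time), stable.

    ``first_peak_times`` may contain NaN for cells without peaks; those
    rows sort after the peaked rows of their cluster, preserving input
    order among themselves.
    """
    clusters = np.asarray(cluster_ids)
    peaks = np.asarray(first_peak_times, dtype=float)
    key = np.where(np.isnan(peaks), np.inf, peaks)
    # lexsort is stable; last key is primary
    return np.lexsort((key, clusters))


def render_kymograph(
    traces: pd.DataFrame,
    cluster_ids: np.ndarray,
    first_peak_times: np.ndarray,
    spec: KymographSpec | None = None,
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Render a kymograph.

    Returns (rgba image of shape (n_cells, n_frames, 4), the row-ordered
    numeric matrix on the normalized scale, and the row-ordered cell
    metadata).  Rendering is a pure function of its inputs.
    """
    spec = spec or KymographSpec()
    if spec.mode == "per_embryo_minmax":
        meta, mat, _ = normalize_traces(traces, "minmax_embryo")
        scaled = mat
    elif spec.mode == "global_zscore":
        meta, mat, _ = normalize_traces(traces, "zscore_embryo")
        scaled = mat
    else:
        raise ValueError(f"unknown kymograph mode {spec.mode!r}")
    order = row_order(cluster_ids, first_peak_times)
    matrix = scaled[order]
    lo, hi = spec.value_range
    clipped = np.clip(matrix, lo, hi)
    cmap = colormaps[spec.cmap]
    image = cmap((clipped - lo) / (hi - lo))
    ordered_meta = meta.iloc[order].reset_index(drop=True)
    ordered_meta["cluster"] = np.asarray(cluster_ids)[order]
    return image, matrix, ordered_meta


def save_kymograph(
    image: np.ndarray, matrix: np.ndarray, png_path, csv_path
) -> None:
    """PNG for viewing plus the numeric matrix as CSV (tests and
    downstream consumers read the CSV, never pixels)."""
    import matplotlib.pyplot as plt

    plt.imsave(png_path, image)
    pd.DataFrame(matrix).to_csv(csv_path, index=False, float_format="%.8g")
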