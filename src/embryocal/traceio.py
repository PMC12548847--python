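"""Movie / label / trace-table I/O and per-cell trace extraction.

Movies are multi-page TIFF stacks (time, y, x) with acquisition metadata
(frame interval, pixel size) in a JSON sidecar, since plain TIFF has no
standard fields for them.  Label images map pixels to cell ids (0 =
background) and come with a cell -> tissue table.  Trace tables are
long-format CSV with columns (embryo_id, cell_id, tissue, frame, time_s,
intensity).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from scipy import ndimage

from .synthdata import TISSUES

logger = logging.getLogger(__name__)

TRACE_COLUMNS = ["embryo_id", "cell_id", "tissue", "frame", "time_s", "intensity"]

DEFAULT_FRAME_INTERVAL_S = 5.0
DEFAULT_PIXEL_SIZE_UM = 0.5


class FormatError(ValueError):
    """Malformed movie or trace file."""


class LabelingError(ValueError):
    """Label image inconsistent with its tissue table."""


@dataclass
class EmbryoMovie:
    """Single-channel timelapse: frames[t, y, x] plus acquisition scale."""

    frames: np.ndarray
    frame_interval_s: float = DEFAULT_FRAME_INTERVAL_S
    pixel_size_um: float = DEFAULT_PIXEL_SIZE_UM
    embryo_id: str = "embryo00"

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames)
        if self.frames.ndim != 3:
            raise FormatError("movie must be a 3D (time, y, x) array")
        if self.frames.shape[0] < 2:
            raise FormatError("movie must have at least 2 frames")
        if np.issubdtype(self.frames.dtype, np.number) and self.frames.min() < 0:
            raise FormatError("movie intensities must be non-negative")

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass
class ROILabelMap:
    """Integer label image (0 = background) with a cell -> tissue table."""

    labels: np.ndarray
    tissue: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 2:
            raise FormatError("label image must be 2D")
        if self.labels.min() < 0:
            raise FormatError("labels must be non-negative integers")
        present = self.cell_ids
        missing = [int(c) for c in present if int(c) not in self.tissue]
        if missing:
            raise LabelingError(f"labels missing from tissue table: {missing}")
        for cid, t in self.tissue.items():
            if t not in TISSUES:
                raise LabelingError(f"unknown tissue {t!r} for cell {cid}")
        for cid in present:
            region = self.labels == cid
            n_comp = ndimage.label(region)[1]
            if n_comp > 1:
                warnings.warn(
                    f"label {int(cid)} is not a connected region", stacklevel=2
                )

    @property
    def cell_ids(self) -> np.ndarray:
        ids = np.unique(self.labels)
        return ids[ids > 0]


# ---------------------------------------------------------------------------
# trace extraction
# ---------------------------------------------------------------------------


def extract_traces(movie: EmbryoMovie, labels: ROILabelMap) -> pd.DataFrame:
    """Per-cell mean-intensity traces from a labeled movie.

    trace[t] is the arithmetic mean of frame t over the cell's pixels.
    Returns the long-format trace table.
    """
    if labels.labels.shape != movie.frames.shape[1:]:
        raise FormatError(
            f"label shape {labels.labels.shape} does not match movie "
            f"frame shape {movie.frames.shape[1:]}"
        )
    frames = movie.frames.reshape(movie.n_frames, -1).astype(float)
    lab_flat = labels.labels.ravel()
    recs = []
    times = movie.times_s
    for cid in labels.cell_ids:
        sel = lab_flat == cid
        if not sel.any():
            warnings.warn(f"label {int(cid)} has no pixels; skipped", stacklevel=2)
            continue
        trace = frames[:, sel].mean(axis=1)
        recs.append(
            pd.DataFrame(
                {
                    "embryo_id": movie.embryo_id,
                    "cell_id": int(cid),
                    "tissue": labels.tissue[int(cid)],
                    "frame": np.arange(movie.n_frames),
                    "time_s": times,
                    "intensity": trace,
                }
            )
        )
    if not recs:
        return pd.DataFrame(columns=TRACE_COLUMNS)
    return pd.concat(recs, ignore_index=True)


# ---------------------------------------------------------------------------
# movie I/O
# ---------------------------------------------------------------------------


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_movie(movie: EmbryoMovie, path: str | Path) -> None:
    """Write a movie as multi-page TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    tifffile.imwrite(path, movie.frames)
    meta = {
        "frame_interval_s": movie.frame_interval_s,
        "pixel_size_um": movie.pixel_size_um,
        "embryo_id": movie.embryo_id,
    }
    _sidecar_path(path).write_text(json.dumps(meta, indent=1))


def read_movie(path: str | Path) -> EmbryoMovie:
    """Read a multi-page TIFF movie; metadata from the sidecar if present,
    otherwise documented defaults (5-s interval) with a logged warning."""
    path = Path(path)
    arr = tifffile.imread(path)
    if arr.ndim != 3:
        raise FormatError(
            f"expected a monochrome stack (time, y, x); got shape {arr.shape}"
        )
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    else:
        logger.warning(
            "no metadata sidecar for %s; assuming frame_interval_s=%s, "
            "pixel_size_um=%s",
            path,
            DEFAULT_FRAME_INTERVAL_S,
            DEFAULT_PIXEL_SIZE_UM,
        )
        meta = {}
    return EmbryoMovie(
        frames=arr,
        frame_interval_s=float(meta.get("frame_interval_s", DEFAULT_FRAME_INTERVAL_S)),
        pixel_size_um=float(meta.get("pixel_size_um", DEFAULT_PIXEL_SIZE_UM)),
        embryo_id=str(meta.get("embryo_id", path.stem)),
    )


def write_labels(labels: ROILabelMap, path: str | Path, tissue_csv: str | Path) -> None:
    """Integer label TIFF plus cell -> tissue CSV table."""
    tifffile.imwrite(Path(path), labels.labels.astype(np.uint16))
    pd.DataFrame(
        {"cell_id": list(labels.tissue), "tissue": list(labels.tissue.values())}
    ).to_csv(tissue_csv, index=False)


def read_labels(path: str | Path, tissue_csv: str | Path) -> ROILabelMap:
    arr = tifffile.imread(Path(path))
    table = pd.read_csv(tissue_csv)
    if not {"cell_id", "tissue"}.issubset(table.columns):
        raise FormatError("tissue table needs columns cell_id, tissue")
    tissue = dict(zip(table["cell_id"].astype(int), table["tissue"]))
    return ROILabelMap(labels=arr, tissue=tissue)


# ---------------------------------------------------------------------------
# trace-table I/O
# ---------------------------------------------------------------------------


def write_traces(traces: pd.DataFrame, path: str | Path) -> None:
    """Long-format CSV, rows grouped by (embryo_id, cell_id), sorted by frame."""
    _validate_trace_table(traces)
    out = traces.sort_values(["embryo_id", "cell_id", "frame"], kind="stable")
    out.to_csv(path, index=False, float_format="%.8g")


def read_traces(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    _validate_trace_table(df)
    return df.sort_values(["embryo_id", "cell_id", "frame"], kind="stable").reset_index(
        drop=True
    )


def _validate_trace_table(df: pd.DataFrame) -> None:
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"trace table missing columns: {missing}")
    lengths = df.groupby(["embryo_id", "cell_id"], sort=False)["frame"].size()
    if lengths.nunique() > 1:
        raise FormatError(
            "non-uniform frame count per cell: "
            f"{sorted(lengths.unique().tolist())}"
        )


def traces_to_wide(traces: pd.DataFrame) -> tuple[pd.DataFrame, np.ndarray]:
    """Pivot the long table to (cell metadata, intensity matrix).

    Returns (index frame with embryo_id/cell_id/tissue per row,
    array of shape (n_cells, n_frames)) in stable cell order.
    """
    _validate_trace_table(traces)
    df = traces.sort_values(["embryo_id", "cell_id", "frame"], kind="stable")
    meta = (
        df[["embryo_id", "cell_id", "tissue"]]
        .drop_duplicates(["embryo_id", "cell_id"])
        .reset_index(drop=True)
    )
    n_frames = df.groupby(["embryo_id", "cell_id"], sort=False)["frame"].size().iloc[0]
    mat = df["intensity"].to_numpy().reshape(len(meta), n_frames)
    return meta, mat


def wide_to_traces(
    meta: pd.DataFrame, mat: np.ndarray, frame_interval_s: float = 5.0
) -> pd.DataFrame:
    """Inverse of :func:`traces_to_wide`."""
    n_cells, n_frames = mat.shape
    return pd.DataFrame(
        {
            "embryo_id": np.repeat(meta["embryo_id"].to_numpy(), n_frames),
            "cell_id": np.repeat(meta["cell_id"].to_numpy(), n_frames),
            "tissue": np.repeat(meta["tissue"].to_numpy(), n_frames),
            "frame": np.tile(np.arange(n_frames), n_cells),
            "time_s": np.tile(np.arange(n_frames) * frame_interval_s, n_cells),
            "intensity": mat.ravel(),
        }
    )
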