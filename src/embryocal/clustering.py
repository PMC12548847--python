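"""Unbiased grouping of cells by calcium-trace dynamics.

Pairwise similarity is the largest positive value of the normalized
signal cross-correlation over all integer lags, which compares trace
*shape* and is tolerant to modest misalignment of peak times.  Density
clustering (HDBSCAN) is run on the distance 1 - similarity; in the
global (cross-embryo) mode traces are z-scored per embryo first and the
HDBSCAN outlier class is kept as an additional cluster of asynchronous
spikers.  Cluster ids are renumbered in ascending order of each
cluster's mean transient count, so the most quiescent group is 0.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.cluster import HDBSCAN

from .traceio import traces_to_wide

OUTLIER = -1


class NormalizationError(ValueError):
    """Zero dynamic range makes normalization undefined."""


# ---------------------------------------------------------------------------
# normalization
# ---------------------------------------------------------------------------


def normalize_traces(
    traces: pd.DataFrame, mode: str = "minmax_embryo"
) -> tuple[pd.DataFrame, np.ndarray, pd.DataFrame]:
    """Normalize a long trace table with embryo-wide constants.

    ``minmax_embryo``: (x - min) / (max - min) with min/max over all
    traces of the embryo jointly.  ``zscore_embryo``: (x - mean) / SD
    with mean/SD pooled over all trace values of the embryo.  Returns
    (meta, normalized matrix, per-embryo constants table).
    """
    meta, mat = traces_to_wide(traces)
    out = np.empty_like(mat, dtype=float)
    consts = []
    for embryo, grp in meta.groupby("embryo_id", sort=False):
        rows = grp.index.to_numpy()
        block = mat[rows]
        if mode == "minmax_embryo":
            lo, hi = float(block.min()), float(block.max())
            if hi == lo:
                raise NormalizationError(
                    f"embryo {embryo}: zero intensity range, cannot min-max normalize"
                )
            out[rows] = (block - lo) / (hi - lo)
            consts.append({"embryo_id": embryo, "c0": lo, "c1": hi - lo})
        elif mode == "zscore_embryo":
            mu, sd = float(block.mean()), float(block.std())
            if sd == 0:
                raise NormalizationError(
                    f"embryo {embryo}: zero variance, cannot z-score"
                )
            out[rows] = (block - mu) / sd
            consts.append({"embryo_id": embryo, "c0": mu, "c1": sd})
        else:
            raise ValueError(f"unknown normalization mode {mode!r}")
    return meta, out, pd.DataFrame(consts)


class TraceNormalizer(BaseEstimator):
    """Estimator facade over :func:`normalize_traces` for long tables."""

    def __init__(self, mode: str = "minmax_embryo"):
        self.mode = mode

    def fit_transform(self, traces: pd.DataFrame):
        meta, mat, consts = normalize_traces(traces, self.mode)
        self.meta_ = meta
        self.constants_ = consts
        return mat


# ---------------------------------------------------------------------------
# similarity
# ---------------------------------------------------------------------------


def similarity(a: np.ndarray, b: np.ndarray) -> float:
    """Largest positive value of the normalized cross-correlation of two
    traces over all integer lags, clipped to [0, 1].

    Traces are mean-subtracted and L2-normalized, so the result is
    invariant to positive affine rescaling.  Two constant traces are
    maximally similar (1); a constant and a non-constant trace are
    dissimilar (0).
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ValueError("traces must be equal-length 1D arrays (length >= 2)")
    a0 = a - a.mean()
    b0 = b - b.mean()
    na, nb = np.linalg.norm(a0), np.linalg.norm(b0)
    if na == 0.0 and nb == 0.0:
        return 1.0
    if na == 0.0 or nb == 0.0:
        return 0.0
    cc = np.correlate(a0, b0, mode="full") / (na * nb)
    return float(np.clip(cc.max(), 0.0, 1.0))


def similarity_matrix(traces: np.ndarray) -> np.ndarray:
    """Pairwise :func:`similarity` for rows of (n_cells, n_frames),
    computed with FFT cross-correlation over all lags."""
    x = np.asarray(traces, dtype=float)
    n_cells, n_frames = x.shape
    xc = x - x.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    nfft = int(2 ** np.ceil(np.log2(2 * n_frames - 1)))
    f = np.fft.rfft(xc, n=nfft)
    s = np.empty((n_cells, n_cells))
    const = norms == 0.0
    for i in range(n_cells):
        cc = np.fft.irfft(f[i][None, :] * np.conj(f), n=nfft)
        peak = cc.max(axis=1)
        denom = norms[i] * norms
        with np.errstate(invalid="ignore", divide="ignore"):
            si = np.clip(peak / denom, 0.0, 1.0)
        si[const | (norms[i] == 0.0)] = 0.0
        if const[i]:
            si[const] = 1.0
        s[i] = si
    s[np.arange(n_cells), np.arange(n_cells)] = np.where(const, 1.0, 1.0)
    s = 0.5 * (s + s.T)  # enforce exact symmetry against fp round-off
    np.fill_diagonal(s, 1.0)
    return s


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


@dataclass
class ClusterLabels:
    """Per-cell cluster assignment with provenance parameters."""

    labels: np.ndarray  # relabeled ids, ascending mean transient count
    is_outlier: np.ndarray
    mode: str
    min_cluster_size: int
    min_samples: int

    def table(self, meta: pd.DataFrame) -> pd.DataFrame:
        out = meta.copy()
        out["cluster"] = self.labels
        out["is_outlier"] = self.is_outlier
        return out


def cluster_traces(
    sim: np.ndarray,
    peak_counts: np.ndarray,
    min_cluster_size: int = 20,
    min_samples: int = 10,
    mode: str = "global",
) -> ClusterLabels:
    """HDBSCAN on the precomputed distance 1 - similarity.

    In ``global`` mode the outlier class becomes one extra cluster; in
    ``per_embryo`` mode outliers keep their native flag and are excluded
    from relabeling.  Cluster ids are then renumbered in ascending order
    of the mean transient count of their member cells.
    """
    sim = np.asarray(sim, dtype=float)
    counts = np.asarray(peak_counts, dtype=float)
    n = sim.shape[0]
    if sim.shape != (n, n) or counts.shape != (n,):
        raise ValueError("similarity must be square and match peak_counts")
    if min_cluster_size < 2:
        raise ValueError("min_cluster_size must be >= 2")
    if n < min_cluster_size:
        warnings.warn(
            "fewer cells than min_cluster_size; everything is an outlier",
            stacklevel=2,
        )
        raw = np.full(n, OUTLIER)
    elif np.all(1.0 - sim < 1e-12):
        raw = np.zeros(n, dtype=int)  # all traces identical: one core cluster
    else:
        dist = 1.0 - sim
        np.fill_diagonal(dist, 0.0)
        dist = np.clip(dist, 0.0, None)
        raw = HDBSCAN(
            min_cluster_size=int(min_cluster_size),
            min_samples=int(min_samples),
            metric="precomputed",
            copy=True,
        ).fit_predict(dist)
    is_outlier = raw == OUTLIER
    labels = raw.copy()
    if mode == "global":
        if is_outlier.any():
            labels = labels.copy()
            labels[is_outlier] = raw.max() + 1  # outlier class as a cluster
        order_ids = np.unique(labels)
    elif mode == "per_embryo":
        order_ids = np.unique(labels[~is_outlier])
    else:
        raise ValueError(f"unknown mode {mode!r}")
    # renumber ascending by mean transient count
    means = [
        (counts[labels == cid].mean() if (labels == cid).any() else np.inf, cid)
        for cid in order_ids
    ]
    remap = {cid: new for new, (_, cid) in enumerate(sorted(means))}
    out = np.array(
        [remap.get(l, OUTLIER) for l in labels], dtype=int
    )
    return ClusterLabels(
        labels=out,
        is_outlier=is_outlier,
        mode=mode,
        min_cluster_size=min_cluster_size,
        min_samples=min_samples,
    )


def relabel_by_activity(labels: np.ndarray, peak_counts: np.ndarray) -> np.ndarray:
    """Renumber cluster ids so they ascend with mean transient count."""
    labels = np.asarray(labels)
    counts = np.asarray(peak_counts, dtype=float)
    ids = np.unique(labels)
    means = sorted((counts[labels == cid].mean(), cid) for cid in ids)
    remap = {cid: new for new, (_, cid) in enumerate(means)}
    return np.array([remap[l] for l in labels], dtype=int)


class TraceClusterer(ClusterMixin, BaseEstimator):
    """End-to-end dynamics clustering: normalize -> similarity -> HDBSCAN.

    ``fit`` takes a long trace table plus per-cell peak counts (aligned
    with the stable cell order of :func:`traceio.traces_to_wide`).
    Fitted attributes: ``similarity_``, ``labels_``, ``is_outlier_``,
    ``meta_``.
    """

    def __init__(
        self,
        min_cluster_size: int = 20,
        min_samples: int = 10,
        mode: str = "global",
        normalization: str | None = None,
    ):
        self.min_cluster_size = min_cluster_size
        self.min_samples = min_samples
        self.mode = mode
        self.normalization = normalization  # default: by mode

    def fit(self, traces: pd.DataFrame, peak_counts=None):
        norm_mode = self.normalization or (
            "zscore_embryo" if self.mode == "global" else "minmax_embryo"
        )
        meta, mat, _ = normalize_traces(traces, norm_mode)
        if peak_counts is None:
            raise ValueError("peak_counts per cell are required for relabeling")
        sim = similarity_matrix(mat)
        result = cluster_traces(
            sim,
            np.asarray(peak_counts, dtype=float),
            min_cluster_size=self.min_cluster_size,
            min_samples=self.min_samples,
            mode=self.mode,
        )
        self.meta_ = meta
        self.similarity_ = sim
        self.labels_ = result.labels
        self.is_outlier_ = result.is_outlier
        self.result_ = result
        return self

    def fit_predict(self, traces, peak_counts=None):
        return self.fit(traces, peak_counts).labels_
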