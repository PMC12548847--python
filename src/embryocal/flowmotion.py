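"""Spatiotemporal analysis of calcium-signal propagation.

The calcium channel is binarized at mean + 0.5 SD (computed over all
pixels and frames) so that tissue motion bleeding into the reporter
channel is suppressed before tracking.  Signal motion is summarized in
the motion-sensing-superpixel style: a regular grid of superpixel seeds
is advected frame-to-frame by the mean dense optical flow inside each
seed's patch (masked to signal regions), yielding per-seed tracks and a
mean temporal flow map.  Two dense-flow backends are exposed: an
iterative Lucas-Kanade default and TV-L1, the robust choice for the
large displacements of epiblast waves.  Embryos are brought into a
common frame by rotating the first principal axis of the cell centroids
vertical, extraembryonic ectoderm (ExE) on top.  Wave speed is the
least-squares slope of front position (half-max crossing, sub-pixel
interpolated) against time.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import linregress
from skimage.registration import optical_flow_ilk, optical_flow_tvl1


class OrientationError(ValueError):
    """Centroid cloud too isotropic to define a long axis."""


class EstimationError(ValueError):
    """Not enough data for a wave estimate."""


# ---------------------------------------------------------------------------
# binarization
# ---------------------------------------------------------------------------


def binarize_signal(movie: np.ndarray) -> np.ndarray:
    """Boolean mask: movie > mean + 0.5*SD (global over pixels and frames)."""
    movie = np.asarray(movie, dtype=float)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise ValueError("movie must be (time, y, x) with >= 2 frames")
    sd = movie.std()
    if sd == 0.0:
        warnings.warn("constant movie; empty signal mask", stacklevel=2)
        return np.zeros(movie.shape, dtype=bool)
    return movie > movie.mean() + 0.5 * sd


# ---------------------------------------------------------------------------
# orientation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class OrientationTransform:
    """Rotation (about the centroid mean) making the long axis vertical
    with the ExE mean on top (larger y in math convention)."""

    angle_rad: float
    center: np.ndarray

    @property
    def matrix(self) -> np.ndarray:
        c, s = np.cos(self.angle_rad), np.sin(self.angle_rad)
        return np.array([[c, -s], [s, c]])

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return (pts - self.center) @ self.matrix.T + self.center


def orient_vertical(
    centroids: np.ndarray, tissues, min_eigen_ratio: float = 1.05
) -> OrientationTransform:
    """Rotation aligning the first principal axis of the centroids with
    the vertical, choosing the 180-degree alternative that puts the mean
    ExE centroid above the mean of the other tissues."""
    pts = np.asarray(centroids, dtype=float)
    tissues = np.asarray(tissues)
    if pts.shape[0] < 3:
        raise OrientationError("need at least 3 centroids")
    if not (tissues == "ExE").any():
        raise OrientationError("need at least one ExE-labeled cell")
    center = pts.mean(axis=0)
    cov = np.cov((pts - center).T)
    evals, evecs = np.linalg.eigh(cov)
    if evals[1] <= 0:
        raise OrientationError("degenerate centroid cloud (all points coincide)")
    # collinear clouds (evals[0] ~ 0) are maximally anisotropic and fine
    if evals[1] / max(evals[0], 1e-300 * evals[1]) < min_eigen_ratio:
        raise OrientationError("centroid cloud is isotropic; long axis ambiguous")
    principal = evecs[:, 1]  # largest eigenvalue
    # rotate principal axis onto +y
    angle = np.arctan2(principal[0], principal[1])
    tf = OrientationTransform(angle_rad=float(angle), center=center)
    rotated = tf.apply(pts)
    exe_y = rotated[tissues == "ExE", 1].mean()
    rest_y = rotated[tissues != "ExE", 1].mean()
    if exe_y < rest_y:
        tf = OrientationTransform(angle_rad=float(angle + np.pi), center=center)
    return tf


# ---------------------------------------------------------------------------
# superpixel flow tracking
# ---------------------------------------------------------------------------


@dataclass
class FlowField:
    """Dense per-frame-pair flow plus superpixel tracks and mean map.

    ``flows[t]`` holds the (dy, dx) displacement field from frame t to
    t+1 in pixels/frame; ``tracks`` is (n_seeds, n_frames, 2) seed
    positions (row, col); ``mean_flow`` is (n_seeds, 2), the per-seed
    average displacement over frames where the seed saw signal.
    """

    flows: np.ndarray
    seeds: np.ndarray
    tracks: np.ndarray
    mean_flow: np.ndarray
    seed_active: np.ndarray = field(default_factory=lambda: np.array([]))


def _dense_flow(frame0, frame1, method: str) -> np.ndarray:
    """Displacement (dy, dx) describing motion from frame0 to frame1."""
    if method == "tvl1":
        v = optical_flow_tvl1(frame1, frame0)
    elif method == "dense_default":
        v = optical_flow_ilk(frame1, frame0)
    else:
        raise ValueError(f"unknown flow method {method!r}")
    # skimage returns the field warping the moving image (frame0) onto the
    # reference (frame1): for content moving +d between frames the field
    # is -d at the new location; negate to report motion direction.
    return -np.stack(v)


def track_flow(
    movie: np.ndarray,
    mask: np.ndarray | None = None,
    n_superpixels: int = 200,
    method: str = "dense_default",
) -> FlowField:
    """Motion-sensing-superpixel tracking of the (masked) signal.

    Seeds start on a regular grid; each frame pair, every seed moves by
    the mean dense flow over its patch restricted to the signal mask.
    The mean temporal flow per seed averages its per-frame displacements
    over frames where its patch contained signal.
    """
    movie = np.asarray(movie, dtype=float)
    if mask is None:
        mask = binarize_signal(movie)
    if n_superpixels < 4:
        raise ValueError("n_superpixels must be >= 4")
    n_frames, h, w = movie.shape
    if not mask.any():
        warnings.warn("empty signal mask; empty flow field", stacklevel=2)
        empty = np.zeros((0, 2))
        return FlowField(
            flows=np.zeros((n_frames - 1, 2, h, w)),
            seeds=empty,
            tracks=np.zeros((0, n_frames, 2)),
            mean_flow=empty,
            seed_active=np.zeros(0, dtype=bool),
        )
    grid = int(np.round(np.sqrt(n_superpixels)))
    step_y, step_x = h / grid, w / grid
    ys = (np.arange(grid) + 0.5) * step_y
    xs = (np.arange(grid) + 0.5) * step_x
    seeds = np.array([(y, x) for y in ys for x in xs])
    half_y, half_x = step_y / 2, step_x / 2
    flows = np.empty((n_frames - 1, 2, h, w))
    for t in range(n_frames - 1):
        flows[t] = _dense_flow(movie[t], movie[t + 1], method)
    tracks = np.zeros((len(seeds), n_frames, 2))
    tracks[:, 0] = seeds
    sums = np.zeros((len(seeds), 2))
    counts = np.zeros(len(seeds))
    for t in range(n_frames - 1):
        m = mask[t]
        for i in range(len(seeds)):
            y, x = tracks[i, t]
            y0, y1 = int(max(0, y - half_y)), int(min(h, y + half_y + 1))
            x0, x1 = int(max(0, x - half_x)), int(min(w, x + half_x + 1))
            patch_mask = m[y0:y1, x0:x1]
            if patch_mask.any():
                dy = flows[t, 0, y0:y1, x0:x1][patch_mask].mean()
                dx = flows[t, 1, y0:y1, x0:x1][patch_mask].mean()
                sums[i] += (dy, dx)
                counts[i] += 1
            else:
                dy = dx = 0.0
            tracks[i, t + 1] = (
                np.clip(y + dy, 0, h - 1),
                np.clip(x + dx, 0, w - 1),
            )
    with np.errstate(invalid="ignore"):
        mean_flow = np.where(counts[:, None] > 0, sums / counts[:, None], 0.0)
    return FlowField(
        flows=flows,
        seeds=seeds,
        tracks=tracks,
        mean_flow=mean_flow,
        seed_active=counts > 0,
    )


# ---------------------------------------------------------------------------
# wave-speed estimation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class WaveEstimate:
    speed_um_s: float
    direction: str
    duration_s: float
    r_squared: float


def locate_front(
    movie: np.ndarray,
    threshold: float | None = None,
    axis: int = 1,
) -> np.ndarray:
    """Per-frame front position (pixels, sub-pixel interpolated) along
    ``axis`` of the frame (1 = rows, 2 = columns).

    The frame is averaged over the perpendicular dimension; the front is
    the furthest position where the profile crosses the binarization
    threshold (default mean + 0.5 SD of the movie), linearly
    interpolated between samples.  Frames with no above-threshold signal
    give NaN.
    """
    movie = np.asarray(movie, dtype=float)
    if threshold is None:
        threshold = movie.mean() + 0.5 * movie.std()
    perp = 2 if axis == 1 else 1
    profiles = movie.mean(axis=perp)  # (n_frames, extent)
    fronts = np.full(movie.shape[0], np.nan)
    for t, prof in enumerate(profiles):
        above = prof > threshold
        if not above.any():
            continue
        last = int(np.flatnonzero(above).max())
        if last + 1 < prof.size and prof[last] != prof[last + 1]:
            frac = (prof[last] - threshold) / (prof[last] - prof[last + 1])
            fronts[t] = last + np.clip(frac, 0.0, 1.0)
        else:
            fronts[t] = float(last)
    return fronts


def estimate_wave(
    front_positions_um: np.ndarray,
    times_s: np.ndarray,
    axis_orientation: str = "apical_basal",
) -> WaveEstimate:
    """Least-squares regression of front position on time.

    Direction labels: positive slope means motion toward increasing
    position along the axis ("apical->basal" for an apical-basal axis
    pointing basally, "distal"/"proximal" for an embryo long axis).
    """
    pos = np.asarray(front_positions_um, dtype=float)
    t = np.asarray(times_s, dtype=float)
    ok = np.isfinite(pos) & np.isfinite(t)
    if ok.sum() < 3:
        raise EstimationError("need at least 3 front positions")
    fit = linregress(t[ok], pos[ok])
    speed = abs(fit.slope)
    if axis_orientation == "apical_basal":
        direction = "apical->basal" if fit.slope >= 0 else "basal->apical"
    elif axis_orientation == "proximal_distal":
        direction = "distal" if fit.slope >= 0 else "proximal"
    else:
        direction = "mixed"
    return WaveEstimate(
        speed_um_s=float(speed),
        direction=direction,
        duration_s=float(t[ok].max() - t[ok].min()),
        r_squared=float(fit.rvalue**2),
    )


def wave_speed_from_movie(
    movie: np.ndarray,
    pixel_size_um: float,
    frame_interval_s: float,
    axis: int = 1,
    axis_orientation: str = "apical_basal",
) -> WaveEstimate:
    """Binarize -> locate the half-max front per frame -> regress.

    Frames where the front has saturated at its final position (the wave
    has crossed the whole cell) are excluded from the regression, as are
    frames before signal onset.
    """
    fronts = locate_front(movie, axis=axis)
    valid = np.isfinite(fronts)
    if valid.sum() < 3:
        raise EstimationError("fewer than 3 frames with signal")
    f_max = np.nanmax(fronts)
    moving = valid & (fronts < f_max - 0.25)
    if moving.sum() < 3:
        # too few strictly-moving frames: admit the first saturated frame
        reached = np.flatnonzero(valid & ~moving)
        if reached.size:
            moving[reached[0]] = True
    if moving.sum() < 3:
        moving = valid
    times = np.arange(movie.shape[0]) * frame_interval_s
    return estimate_wave(
        fronts[moving] * pixel_size_um, times[moving], axis_orientation
    )
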