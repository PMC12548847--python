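"""Synthetic embryo datasets with known ground truth.

This module generates the kinds of data the analysis pipeline consumes:
per-cell fluorescence traces of a calcium reporter sampled at a fixed
frame interval, pixel movies of propagating calcium waves, and
inhibitor-experiment transient-count records.  Every generated object is
paired with a :class:`GroundTruth` record so that downstream stages
(de-trending, peak detection, clustering, flow analysis) can be scored
against the truth.

The default study conditions mirror single mid-sagittal optical sections
of E5.5 mouse egg cylinders imaged every 5 s for 10 min, with four
tissue classes (epiblast, ExE, emVE, exVE).  Transients are homogeneous
Poisson events per cell; each event adds a calcium-indicator-like kernel

    f(t) = A * (1 - exp(-t / tau_r)) * exp(-t / tau_d),   t >= 0,

whose decay constant ``tau_d`` is solved numerically so that the
kernel's full width at half maximum equals the requested value
(default 20 s, the cross-tissue transient duration scale).  Traces sit
on a slowly drifting baseline with additive Gaussian noise.
"""

from __future__ import annotations

import dataclasses
import json
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

TISSUES = ("epiblast", "ExE", "emVE", "exVE")

#: Tissue counts of the reference single-section dataset (1,126 cells).
REFERENCE_TISSUE_COUNTS = {"epiblast": 323, "ExE": 430, "emVE": 205, "exVE": 168}

#: Default expected transients per cell per 10 min, calibrated so that the
#: Poisson active fraction 1 - exp(-rate) matches the observed per-tissue
#: active-cell percentages (10/38/40/56%).  These are calibration values,
#: not measured rates.
DEFAULT_TISSUE_RATES = {"epiblast": 0.11, "ExE": 0.48, "emVE": 0.51, "exVE": 0.82}


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


class LayoutError(ValueError):
    """Invalid embryo layout."""


# ---------------------------------------------------------------------------
# configuration / layout / truth containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the trace simulator.

    All times in seconds, intensities in arbitrary units (AU).
    ``tissue_rates`` are expected transient counts per cell per 10 min;
    they are rescaled for other durations.
    """

    frame_interval_s: float = 5.0
    duration_s: float = 600.0
    tissue_rates: Mapping[str, float] = field(
        default_factory=lambda: dict(DEFAULT_TISSUE_RATES)
    )
    kernel_amplitude: float = 100.0
    kernel_fwhm_s: float = 20.0
    # rise constant of one frame interval: slow enough that 5-s sampling
    # resolves the peak (any sampling phase sees >= ~85% of the nominal
    # amplitude), fast enough for indicator-like asymmetry
    kernel_rise_s: float = 5.0
    baseline_level: float = 100.0
    drift_amplitude: float = 20.0
    noise_sd: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.frame_interval_s <= 0:
            raise ConfigurationError("frame_interval_s must be positive")
        if self.duration_s <= 0:
            raise ConfigurationError("duration_s must be positive")
        n = self.duration_s / self.frame_interval_s
        if abs(n - round(n)) > 1e-9:
            raise ConfigurationError(
                "duration_s must be a positive multiple of frame_interval_s"
            )
        if any(r < 0 for r in self.tissue_rates.values()):
            raise ConfigurationError("tissue rates must be non-negative")
        if self.kernel_fwhm_s <= self.frame_interval_s / 2:
            raise ConfigurationError("kernel_fwhm_s must exceed frame_interval_s/2")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")

    @property
    def n_frames(self) -> int:
        """Frame count, including the frame at t = 0."""
        return int(round(self.duration_s / self.frame_interval_s)) + 1

    @property
    def times_s(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval_s


@dataclass(frozen=True)
class EmbryoLayout:
    """Cell centroid geometry of one embryo section.

    ``centroids_um`` maps cell_id -> (x, y) in micrometres; ``tissue``
    maps cell_id -> tissue name; ``adjacency`` is a symmetric neighbour
    relation used by wave simulation.
    """

    centroids_um: Mapping[int, tuple[float, float]]
    tissue: Mapping[int, str]
    adjacency: Mapping[int, frozenset] = field(default_factory=dict)
    pixel_size_um: float = 0.5
    embryo_id: str = "embryo00"

    def __post_init__(self) -> None:
        if self.pixel_size_um <= 0:
            raise LayoutError("pixel_size_um must be positive")
        for cid in self.centroids_um:
            if cid not in self.tissue:
                raise LayoutError(f"cell {cid} has no tissue label")
        for cid, t in self.tissue.items():
            if t not in TISSUES:
                raise LayoutError(f"unknown tissue {t!r} for cell {cid}")
        for a, nbrs in self.adjacency.items():
            for b in nbrs:
                if a not in self.adjacency.get(b, frozenset()):
                    raise LayoutError("adjacency must be symmetric")

    @property
    def cell_ids(self) -> list:
        return sorted(self.centroids_um)


@dataclass
class TrueEvent:
    """One simulated transient: Poisson onset plus kernel peak location."""

    cell_id: int
    onset_s: float
    peak_s: float
    peak_frame: int


@dataclass
class GroundTruth:
    """Truth channel of a simulation (events, waves, condition effects)."""

    events: list = field(default_factory=list)  # list[TrueEvent]
    wave_origin: int | None = None
    wave_speed_um_s: float | None = None
    wave_cells: list = field(default_factory=list)
    effect_multipliers: dict = field(default_factory=dict)

    def events_by_cell(self) -> dict:
        out: dict[int, list[TrueEvent]] = {}
        for ev in self.events:
            out.setdefault(ev.cell_id, []).append(ev)
        return out

    def to_json(self) -> str:
        payload = dataclasses.asdict(self)
        return json.dumps(payload, default=list, indent=1)


# ---------------------------------------------------------------------------
# transient kernel
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TransientKernel:
    """Rise-times-decay transient shape with calibrated FWHM."""

    amplitude: float
    tau_rise_s: float
    tau_decay_s: float

    @property
    def t_peak_s(self) -> float:
        return self.tau_rise_s * math.log1p(self.tau_decay_s / self.tau_rise_s)

    def __call__(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        raw = np.where(
            t >= 0.0,
            -np.expm1(-np.clip(t, 0.0, None) / self.tau_rise_s)
            * np.exp(-np.clip(t, 0.0, None) / self.tau_decay_s),
            0.0,
        )
        peak = -math.expm1(-self.t_peak_s / self.tau_rise_s) * math.exp(
            -self.t_peak_s / self.tau_decay_s
        )
        return self.amplitude * raw / peak

    def fwhm_s(self) -> float:
        """Numerically measured full width at half maximum."""
        tp = self.t_peak_s
        half = self.amplitude / 2.0

        def g(t: float) -> float:
            return float(self(np.array([t]))[0]) - half

        t_left = brentq(g, 1e-12, tp)
        hi = tp
        while g(hi) > 0:
            hi = tp + (hi - tp) * 2 + self.tau_decay_s
        t_right = brentq(g, tp, hi)
        return t_right - t_left


def calibrate_kernel(
    amplitude: float, fwhm_s: float, rise_s: float, tol_s: float = 1e-3
) -> TransientKernel:
    """Solve the decay constant so the kernel FWHM equals ``fwhm_s``.

    Bisection on tau_d; FWHM is monotone increasing in the decay time.
    """
    if fwhm_s <= 0 or rise_s <= 0:
        raise ConfigurationError("fwhm_s and rise_s must be positive")

    def width(tau_d: float) -> float:
        return TransientKernel(amplitude, rise_s, tau_d).fwhm_s()

    lo, hi = fwhm_s * 1e-3, fwhm_s * 4
    while width(hi) < fwhm_s:
        hi *= 2
    while width(lo) > fwhm_s:
        lo *= 0.5
    while hi - lo > tol_s:
        mid = 0.5 * (lo + hi)
        if width(mid) < fwhm_s:
            lo = mid
        else:
            hi = mid
    return TransientKernel(amplitude, rise_s, 0.5 * (lo + hi))


# ---------------------------------------------------------------------------
# layout builders
# ---------------------------------------------------------------------------


def make_embryo_layout(
    n_per_tissue: Mapping[str, int] | None = None,
    pixel_size_um: float = 0.5,
    embryo_id: str = "embryo00",
    seed: int = 0,
) -> EmbryoLayout:
    """Build a schematic egg-cylinder layout (ExE on top, epiblast below,
    VE flanking) with grid-like adjacency.  Geometry is coarse: it only
    needs plausible centroids and tissue labels for orientation and wave
    tests, not anatomical fidelity.
    """
    if n_per_tissue is None:
        n_per_tissue = {"epiblast": 8, "ExE": 8, "emVE": 6, "exVE": 6}
    rng = np.random.default_rng(seed)
    centroids: dict[int, tuple[float, float]] = {}
    tissue: dict[int, str] = {}
    cid = 1
    # column bands: epiblast lower core (y in [0, 40)), ExE upper core
    # (y in [50, 90)), emVE flanks epiblast, exVE flanks ExE.
    bands = {
        "epiblast": (10.0, 0.0, 40.0),
        "ExE": (10.0, 50.0, 90.0),
        "emVE": (-12.0, 0.0, 40.0),
        "exVE": (-12.0, 50.0, 90.0),
    }
    for t in TISSUES:
        n = int(n_per_tissue.get(t, 0))
        x0, y_lo, y_hi = bands[t]
        ys = np.linspace(y_lo, y_hi, max(n, 1), endpoint=False)
        for k in range(n):
            jitter = rng.normal(0.0, 1.0, size=2)
            centroids[cid] = (x0 + jitter[0], float(ys[k]) + jitter[1])
            tissue[cid] = t
            cid += 1
    ids = sorted(centroids)
    pts = np.array([centroids[i] for i in ids])
    adjacency: dict[int, set] = {i: set() for i in ids}
    if len(ids) > 1:
        # neighbours: mutual proximity within 15 um
        d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
        for a_idx, a in enumerate(ids):
            for b_idx, b in enumerate(ids):
                if a < b and d[a_idx, b_idx] < 15.0:
                    adjacency[a].add(b)
                    adjacency[b].add(a)
    return EmbryoLayout(
        centroids_um=centroids,
        tissue=tissue,
        adjacency={k: frozenset(v) for k, v in adjacency.items()},
        pixel_size_um=pixel_size_um,
        embryo_id=embryo_id,
    )


def make_cohort_layouts(
    n_embryos: int = 14,
    tissue_counts: Mapping[str, int] | None = None,
    seed: int = 0,
) -> list:
    """Split cohort tissue totals (default: the 1,126-cell reference
    split 323/430/205/168) across embryos as evenly as possible."""
    counts = dict(tissue_counts or REFERENCE_TISSUE_COUNTS)
    layouts = []
    for e in range(n_embryos):
        per = {
            t: counts[t] // n_embryos + (1 if e < counts[t] % n_embryos else 0)
            for t in counts
        }
        layouts.append(
            make_embryo_layout(per, embryo_id=f"embryo{e:02d}", seed=seed + e)
        )
    return layouts


# ---------------------------------------------------------------------------
# trace simulation
# ---------------------------------------------------------------------------


def simulate_embryo_dataset(
    config: SimConfig,
    layout: EmbryoLayout,
    min_event_separation_s: float = 0.0,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Simulate one embryo's per-cell traces.

    Returns a long-format trace table (embryo_id, cell_id, tissue, frame,
    time_s, intensity) and the ground truth.  Event counts per cell are
    Poisson at the cell's tissue rate (rescaled to ``duration_s``); event
    onsets are uniform on [0, duration].  Identical (config, layout)
    inputs give bit-identical output.

    ``min_event_separation_s`` > 0 thins events closer than the given
    refractory interval to their predecessor (keeping the earlier one).
    The default (0, pure Poisson) is the study condition; the refractory
    option exists for detector benchmarks, where two events inside one
    transient width are indistinguishable by construction.
    """
    rng = np.random.default_rng(config.seed)
    kernel = calibrate_kernel(
        config.kernel_amplitude, config.kernel_fwhm_s, config.kernel_rise_s
    )
    times = config.times_s
    n_frames = config.n_frames
    truth = GroundTruth()
    rows_id, rows_tissue, rows_intensity = [], [], []
    drift_period = 2.0 * config.duration_s  # >= duration: at most half a cycle
    for cid in layout.cell_ids:
        t_name = layout.tissue[cid]
        if t_name not in config.tissue_rates:
            raise LayoutError(f"no rate configured for tissue {t_name!r}")
        rate = config.tissue_rates[t_name] * config.duration_s / 600.0
        n_ev = rng.poisson(rate)
        onsets = np.sort(rng.uniform(0.0, config.duration_s, size=n_ev))
        if min_event_separation_s > 0 and onsets.size > 1:
            kept = [onsets[0]]
            for t0 in onsets[1:]:
                if t0 - kept[-1] >= min_event_separation_s:
                    kept.append(t0)
            onsets = np.array(kept)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        trace = config.baseline_level + config.drift_amplitude * np.sin(
            2.0 * np.pi * times / drift_period + phase
        )
        for t0 in onsets:
            trace = trace + kernel(times - t0)
            peak_s = t0 + kernel.t_peak_s
            truth.events.append(
                TrueEvent(
                    cell_id=cid,
                    onset_s=float(t0),
                    peak_s=float(peak_s),
                    peak_frame=int(
                        min(round(peak_s / config.frame_interval_s), n_frames - 1)
                    ),
                )
            )
        if config.noise_sd > 0:
            trace = trace + rng.normal(0.0, config.noise_sd, size=n_frames)
        rows_id.append(cid)
        rows_tissue.append(t_name)
        rows_intensity.append(trace)
    n_cells = len(rows_id)
    df = pd.DataFrame(
        {
            "embryo_id": np.repeat(layout.embryo_id, n_cells * n_frames),
            "cell_id": np.repeat(rows_id, n_frames),
            "tissue": np.repeat(rows_tissue, n_frames),
            "frame": np.tile(np.arange(n_frames), n_cells),
            "time_s": np.tile(times, n_cells),
            "intensity": np.concatenate(rows_intensity)
            if n_cells
            else np.array([]),
        }
    )
    return df, truth


def simulate_single_event_traces(
    n_traces: int,
    config: SimConfig | None = None,
    margin_s: float | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Traces with exactly one isolated transient each, onset uniform in
    the interior of the record (``margin_s`` from both ends, default two
    kernel widths).  Used for duration/amplitude recovery benchmarks."""
    config = config or SimConfig()
    rng = np.random.default_rng(config.seed)
    kernel = calibrate_kernel(
        config.kernel_amplitude, config.kernel_fwhm_s, config.kernel_rise_s
    )
    if margin_s is None:
        margin_s = 2.0 * config.kernel_fwhm_s
    times = config.times_s
    truth = GroundTruth()
    traces = np.empty((n_traces, config.n_frames))
    drift_period = 2.0 * config.duration_s
    for i in range(n_traces):
        t0 = rng.uniform(margin_s, config.duration_s - margin_s)
        phase = rng.uniform(0.0, 2.0 * np.pi)
        tr = (
            config.baseline_level
            + config.drift_amplitude
            * np.sin(2.0 * np.pi * times / drift_period + phase)
            + kernel(times - t0)
        )
        if config.noise_sd > 0:
            tr = tr + rng.normal(0.0, config.noise_sd, size=config.n_frames)
        traces[i] = tr
        peak_s = t0 + kernel.t_peak_s
        truth.events.append(
            TrueEvent(
                cell_id=i,
                onset_s=float(t0),
                peak_s=float(peak_s),
                peak_frame=int(round(peak_s / config.frame_interval_s)),
            )
        )
    n_frames = config.n_frames
    df = pd.DataFrame(
        {
            "embryo_id": np.repeat("synthetic", n_traces * n_frames),
            "cell_id": np.repeat(np.arange(n_traces), n_frames),
            "tissue": np.repeat("emVE", n_traces * n_frames),
            "frame": np.tile(np.arange(n_frames), n_traces),
            "time_s": np.tile(times, n_traces),
            "intensity": traces.ravel(),
        }
    )
    return df, truth


def simulate_archetype_dataset(
    n_embryos: int = 14,
    n_quiescent_per_embryo: int = 9,
    n_per_archetype_per_embryo: int = 3,
    periods_s: Sequence[float] = (60.0, 180.0, 300.0),
    amplitudes: Sequence[float] = (60.0, 100.0, 150.0),
    config: SimConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.Series]:
    """Cohort of embryos containing quiescent cells plus oscillatory
    archetypes with distinct periods (and amplitudes), for clustering
    benchmarks.  Returns the long trace table and a per-(embryo, cell)
    truth label Series ('quiescent', 'period60', ...)."""
    config = config or SimConfig(seed=seed)
    rng = np.random.default_rng(seed)
    kernel_cache = {
        a: calibrate_kernel(a, config.kernel_fwhm_s, config.kernel_rise_s)
        for a in set(amplitudes)
    }
    times = config.times_s
    frames = np.arange(config.n_frames)
    recs = []
    labels = {}
    for e in range(n_embryos):
        embryo_id = f"embryo{e:02d}"
        cid = 1
        specs = [("quiescent", None, None)] * n_quiescent_per_embryo
        for period, amp in zip(periods_s, amplitudes):
            specs += [(f"period{int(period)}", period, amp)] * (
                n_per_archetype_per_embryo
            )
        for label, period, amp in specs:
            if period is None:
                tr = config.baseline_level + rng.normal(
                    0.0, config.noise_sd, size=config.n_frames
                )
            else:
                phase = rng.uniform(0.0, period)
                onsets = np.arange(phase, config.duration_s, period)
                onsets = onsets + rng.normal(0.0, 2.0, size=onsets.size)
                tr = config.baseline_level + rng.normal(
                    0.0, config.noise_sd, size=config.n_frames
                )
                k = kernel_cache[amp]
                for t0 in onsets:
                    tr = tr + k(times - t0)
            recs.append(
                pd.DataFrame(
                    {
                        "embryo_id": embryo_id,
                        "cell_id": cid,
                        "tissue": "emVE" if period else "epiblast",
                        "frame": frames,
                        "time_s": times,
                        "intensity": tr,
                    }
                )
            )
            labels[(embryo_id, cid)] = label
            cid += 1
    df = pd.concat(recs, ignore_index=True)
    truth = pd.Series(labels, name="archetype")
    truth.index.names = ["embryo_id", "cell_id"]
    return df, truth


# ---------------------------------------------------------------------------
# wave movies
# ---------------------------------------------------------------------------


def simulate_wave_movie(
    shape_um: tuple[float, float] = (50.0, 25.0),
    cell_extent_um: tuple[float, float] = (5.0, 45.0),
    speed_um_s: float = 15.41,
    frame_interval_s: float = 0.5,
    pixel_size_um: float = 0.5,
    n_frames: int = 13,
    amplitude: float = 1000.0,
    edge_width_um: float = 1.0,
    noise_sd: float = 20.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Intracellular apical-to-basal wave movie.

    A planar intensity front sweeps down the image (axis 1 of the frame,
    i.e. rows; apical at the top) at constant speed.  Pixels behind the
    front are bright, ahead dark, with a smooth sigmoidal edge.  Returns
    (movie[t, y, x] float array, truth with the exact speed).

    The cell spans rows ``cell_extent_um`` (apical edge to basal edge);
    outside the cell the image stays dark.
    """
    if speed_um_s <= 0:
        raise ConfigurationError("speed_um_s must be positive")
    if speed_um_s * frame_interval_s < pixel_size_um:
        warnings.warn(
            "front moves less than one pixel per frame; estimation "
            "will rely on sub-pixel interpolation",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    h = int(round(shape_um[0] / pixel_size_um))
    w = int(round(shape_um[1] / pixel_size_um))
    y_um = (np.arange(h) + 0.5) * pixel_size_um
    apical_um, basal_um = cell_extent_um
    inside = (y_um >= apical_um) & (y_um <= basal_um)
    movie = np.zeros((n_frames, h, w))
    for t in range(n_frames):
        front = apical_um + speed_um_s * t * frame_interval_s
        arg = np.clip((y_um - front) / edge_width_um, -500.0, 500.0)
        profile = amplitude / (1.0 + np.exp(arg))
        profile = profile * inside
        movie[t] = profile[:, None]
    if noise_sd > 0:
        movie = movie + rng.normal(0.0, noise_sd, size=movie.shape)
    truth = GroundTruth(wave_origin=None, wave_speed_um_s=float(speed_um_s))
    return movie, truth


def simulate_intercellular_wave(
    layout: EmbryoLayout,
    origin: int,
    speed_um_s: float,
    frame_interval_s: float = 5.0,
    pixel_size_um: float = 1.0,
    n_frames: int = 25,
    cell_radius_um: float = 5.0,
    amplitude: float = 1000.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, GroundTruth]:
    """Multicellular wave: cells light up when the radial front from the
    origin cell (distance = speed x elapsed time, measured along graph
    adjacency hops scaled by centroid distance) reaches their centroid."""
    if origin not in layout.centroids_um:
        raise LayoutError(f"origin cell {origin} not in layout")
    if speed_um_s <= 0:
        raise ConfigurationError("speed_um_s must be positive")
    rng = np.random.default_rng(seed)
    pts = np.array([layout.centroids_um[i] for i in layout.cell_ids])
    origin_xy = np.array(layout.centroids_um[origin])
    dist = np.linalg.norm(pts - origin_xy, axis=1)
    lo = pts.min(axis=0) - 3 * cell_radius_um
    hi = pts.max(axis=0) + 3 * cell_radius_um
    w = int(np.ceil((hi[0] - lo[0]) / pixel_size_um))
    h = int(np.ceil((hi[1] - lo[1]) / pixel_size_um))
    yy, xx = np.mgrid[0:h, 0:w]
    px_um = np.stack(
        [lo[0] + (xx + 0.5) * pixel_size_um, lo[1] + (yy + 0.5) * pixel_size_um],
        axis=-1,
    )
    movie = np.zeros((n_frames, h, w))
    arrival = dist / speed_um_s
    participating = []
    for i, cid in enumerate(layout.cell_ids):
        r = np.linalg.norm(px_um - pts[i], axis=-1)
        disk = r <= cell_radius_um
        on_frames = np.arange(n_frames) * frame_interval_s >= arrival[i]
        if on_frames.any():
            participating.append(cid)
        movie[on_frames] += amplitude * disk
    if noise_sd > 0:
        movie = movie + rng.normal(0.0, noise_sd, size=movie.shape)
    truth = GroundTruth(
        wave_origin=origin,
        wave_speed_um_s=float(speed_um_s),
        wave_cells=participating,
    )
    return movie, truth


# ---------------------------------------------------------------------------
# inhibitor experiments
# ---------------------------------------------------------------------------


def simulate_inhibitor_experiment(
    n_embryos: int,
    baseline_rate: float,
    effect_multiplier: float,
    timepoints: Sequence[str] = ("baseline", "treated_30min"),
    recovery_multiplier: float | None = None,
    condition: str = "thapsigargin_10nM",
    seed: int = 0,
) -> pd.DataFrame:
    """Per-embryo transient counts for an inhibitor experiment.

    Counts are Poisson with mean ``baseline_rate`` at baseline,
    ``baseline_rate * effect_multiplier`` after treatment, and
    ``baseline_rate * recovery_multiplier`` at recovery (if present).
    Returns an ExperimentRecord table (embryo_id, condition, timepoint,
    total_transients).
    """
    if not timepoints:
        raise ConfigurationError("timepoints must be non-empty")
    if effect_multiplier < 0:
        raise ConfigurationError("effect_multiplier must be non-negative")
    if n_embryos < 1:
        raise ConfigurationError("n_embryos must be >= 1")
    multipliers = {"baseline": 1.0}
    for tp in timepoints:
        if tp.startswith("treated"):
            multipliers[tp] = effect_multiplier
        elif tp.startswith("recovery"):
            if recovery_multiplier is None:
                raise ConfigurationError(
                    "recovery timepoint requested without recovery_multiplier"
                )
            multipliers[tp] = recovery_multiplier
        elif tp != "baseline":
            raise ConfigurationError(f"unknown timepoint {tp!r}")
    rng = np.random.default_rng(seed)
    rows = []
    for e in range(n_embryos):
        for tp in timepoints:
            mean = baseline_rate * multipliers[tp]
            rows.append(
                {
                    "embryo_id": f"{condition}_e{e:03d}",
                    "condition": condition,
                    "timepoint": tp,
                    "total_transients": int(rng.poisson(mean)),
                }
            )
    return pd.DataFrame(rows)
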