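# Methods

`embryocal` quantifies cytosolic calcium-reporter (GCaMP6f-type) dynamics in
timelapse recordings of peri-implantation mouse embryos: single mid-sagittal
optical sections imaged every 5 s for 10 min, with every cell assigned to one
of four tissues (epiblast, extraembryonic ectoderm ExE, embryonic and
extraembryonic visceral endoderm emVE / exVE). This note documents the models,
conventions and numerical choices behind each stage, and what the synthetic
validation does and does not demonstrate.

## Synthetic embryo generator

The generator is the package's validation instrument: every downstream stage
is benchmarked against its ground truth.

**Traces.** Each cell fires transients as a homogeneous Poisson process at its
tissue's rate (expected events per cell per 10 min). Each event adds a
transient kernel

    f(t) = A · (1 − e^(−t/τ_r)) · e^(−t/τ_d),  t ≥ 0,

rescaled so its maximum equals the amplitude `A` (default 100 AU). The decay
constant τ_d is solved by bisection (tolerance 10⁻³ s) so the kernel's full
width at half maximum equals the user-facing `kernel_fwhm_s` (default 20 s,
the cross-tissue transient duration scale). The rise constant defaults to one
frame interval (5 s): a sampling-adequacy rule — with a faster rise the 5-s
sampling can miss the peak by almost half the amplitude, so the generator's
nominal signal-to-noise ratio would overstate what the traces deliver. With
τ_r = 5 s every sampling phase sees ≥ 95 % of the nominal amplitude. Traces
sit on `baseline_level` (100 AU) plus one slow sinusoid (default amplitude
20 AU = 20 % of the kernel amplitude, period twice the record length — the
simplest trend that exercises the de-trender) plus i.i.d. Gaussian noise
(default SD 20 AU, i.e. SNR 5 in amplitude/noise units). Frame count is
`duration/interval + 1` (the t = 0 frame is included) throughout the package.

**Tissue rates.** Defaults are epiblast 0.11, ExE 0.48, emVE 0.51, exVE 0.82
events per cell per 10 min. These are *calibration* values chosen so the
Poisson active-cell fraction 1 − e^(−rate) matches the observed per-tissue
active-cell percentages (10 / 38 / 40 / 56 %); the underlying per-tissue rates
were never measured directly, and these defaults must not be read as such.

**Refractory option.** `min_event_separation_s` thins events closer than a
given interval to their predecessor. The study condition is pure Poisson
(default 0); detector benchmarks use a 25-s refractory interval because two
events inside one transient width produce a single call *by design* (minimum
call separation), so unresolvable doublets cannot meaningfully count against
recall.

**Waves.** Intracellular wave movies are planar fronts sweeping a cell at
constant speed with a sigmoidal edge (width 1 µm) plus pixel noise; the truth
channel records the exact speed. Multicellular waves activate whole cells in
order of centroid distance from an origin cell. The variable spatial extent of
real waves is represented by the participating-cell set, not modelled
mechanistically.

**Inhibitor experiments.** Per embryo and timepoint, total transient counts
are Poisson with mean `baseline_rate` at baseline and `baseline_rate ×
effect_multiplier` after treatment (optional recovery multiplier). The
thapsigargin calibration is baseline mean 18 and treated mean 1.3 transients
per embryo.

**What the generator does not emulate:** photobleaching, cell movement and
ROI drift, 3-D structure, spatially correlated noise, and mechanistic wave
initiation. Passing synthetic benchmarks therefore demonstrates correctness
of the *algorithms* under the stated statistical assumptions, not performance
on arbitrary real recordings.

## De-trending (asymmetric least squares)

The baseline z of a trace y minimizes Σ wᵢ(yᵢ−zᵢ)² + λ Σ(Δ²zᵢ)² with
wᵢ = p when yᵢ > zᵢ and 1 − p otherwise, iterated until the weight vector is
stable (at most 10 iterations; non-convergence returns the last iterate with
a warning). Defaults λ = 10⁵, p = 0.01: at 5-s sampling this passes 20-s
transients nearly untouched while removing drifts with periods of minutes
(the effective smoothing length λ^(1/4) ≈ 18 frames ≈ 90 s). The solver uses
the symmetric pentadiagonal banded structure (`scipy.linalg.solveh_banded`);
a dense reference implementation is kept for verification (agreement 10⁻⁸
relative on 121-frame traces). De-trending is subtractive by default — the
downstream intensity comparisons are in arbitrary units — with ΔF/F as an
option. Note that with p = 0.01 the baseline tracks the *lower envelope* of
the noise band, leaving a positive offset (≈ +1σ) in the residual's quiet
stretches; downstream metrics account for this (see half-height reference
below).

## Peak detection

**Deterministic reference detector** (`oracle_detect`) — the stand-in for
manual annotation. A frame is called a peak when (i) it is a local maximum
with minimum call separation 3 frames (the higher peak wins inside that
window), (ii) its robust z-score exceeds 3, (iii) its prominence exceeds
1.5 σ̂, and (iv) at least one adjacent frame exceeds half the z-threshold.
Numerical conventions, each load-bearing:

- the noise scale σ̂ is 1.4826 × MAD of *first differences* (÷ √2). The plain
  trace MAD is inflated 25–60 % by transient-occupied frames and residual
  structure and costs real sensitivity; the difference-based estimator is
  insensitive to both.
- the prominence floor (1.5 σ̂) suppresses secondary local maxima riding on a
  transient's noisy decay tail, which otherwise double-call wide transients.
- the neighbour-support condition encodes that genuine transients at this
  sampling span several frames; isolated single-frame excursions are noise.
  It keeps the false-call rate on pure-noise traces at ≈ 2–4 % per 121-frame
  trace at the default threshold.
- the reported peak frame is refined to the argmax of a [1, 2, 1]/4-smoothed
  copy within ±2 frames of the raw local maximum; the raw argmax jitters by
  1–2 frames under noise on flat-topped transients.

**CNN detector** (`CNNPeakDetector`). A classifier maps a symmetric window of
N = 35 samples to the probability that a transient peak lies at the window
centre. Architecture (a configuration choice, not a contract): two valid 1-D
convolutions (kernels 7 and 5; 16 and 32 channels, ReLU) followed by a dense
sigmoid head over all channel × position activations. The head is dense
rather than pooled deliberately: the question is whether the peak is at the
*centre* of the window, and global pooling is translation-invariant and
cannot answer it. Training: binary cross-entropy, Adam (lr 3·10⁻³, batch 128,
80 epochs), implemented in NumPy with hand-derived gradients — the network is
small enough that CPU training takes seconds. Windows centred within ±1 frame
of an annotated peak are positives; negatives are drawn outside a one-frame
guard zone at 4× the positive count (the higher negative share buys
precision). Traces are standardized by median and difference-based σ̂ before
windowing; edges are reflect-padded. An ensemble option (`n_models`) averages
independently initialized nets and is used in benchmarks to damp
training-seed variance. Everything is deterministic under `random_state`.
Calls are local maxima of the per-frame probability above 0.5 with 3-frame
minimum separation.

**Benchmark design.** Two complementary experiments, both at SNR 5 with
±1-frame event matching: (a) *parameter recovery* — train on truth labels,
score against held-out truth (precision/recall ≥ 0.9); (b) *annotator
equivalence* — train on the deterministic detector's calls and measure
event-level agreement with it on held-out traces (F1 ≥ 0.9). The second
mirrors actual practice, where the classifier is trained by the same
annotator it is later compared against.

## Per-peak and per-cell metrics

Peak duration uses the half-height rule at native sampling: start = the last
frame before the rising trace reaches half the peak height, end = the first
frame after the falling trace drops below it, duration = end − start. This
outer convention overestimates a continuous FWHM by up to two frame
intervals. The reference level for "half height" is the median of the
de-trended trace between the flanking peaks (or trace ends), *excluding* ±2
frames around the peak itself so the transient does not inflate its own
reference; this absorbs the positive residual offset left by the asymmetric
de-trender. A "zero" reference mode is available. Crossings are searched only
within the inter-peak interval; unresolved crossings (boundary peaks,
overlapping transients) flag the event truncated, and truncated events report
no duration. Peak intensity is the de-trended value at the peak frame.

Cell summaries: peak count, mean peak intensity, mean duration, and the
oscillation period as the mean peak-to-peak distance — defined only for cells
with ≥ 2 peaks, recorded as NaN (the N/A convention of the tabulated
outputs) otherwise. Tissue summaries add the active-cell percentage
(≥ 1 transient), with emVE kept whole (no DVE subdivision). Percentages are
reported at one-decimal precision.

## Dynamics clustering

Pairwise similarity is the largest positive value of the normalized signal
cross-correlation over all integer lags (mean-subtracted, L2-normalized;
FFT-accelerated for the matrix). This compares trace shape and tolerates
modest peak misalignment. Conventions: a constant trace has similarity 1 with
another constant trace and 0 with any non-constant trace; negative maxima
clip to 0. Clustering runs HDBSCAN (scikit-learn implementation) on the
precomputed distance 1 − s; the transform is a design choice, as is computing
similarity on normalized traces (configurable). Normalization is per embryo:
min–max over all traces of the embryo jointly for per-embryo analyses,
pooled z-score for the global cross-embryo mode. Defaults
`min_cluster_size = 20`, `min_samples = 10` suit the ~1,100-cell scale and
are exposed in configuration. In global mode the HDBSCAN outlier class is
kept as one extra cluster (asynchronous spikers); in per-embryo mode outliers
keep their native flag. Cluster ids are renumbered ascending by mean
transient count of member cells, so the most quiescent group is always 0. A
degenerate all-identical input forms a single core cluster directly. The
archetype benchmark (14 embryos; quiescent cells plus oscillators with 60,
180, 300-s periods) recovers 4 groups — three core clusters plus the
quiescent cells, which land in the outlier-as-cluster group — with mean
adjusted Rand index ≈ 0.9 over ten seeds.

## Kymographs

Rows are cells, columns time points, colour the "magma" map. Per-embryo mode
maps the embryo-wide min–max normalized traces onto [0, 1]; global mode maps
per-embryo z-scores onto the positive range [0, 2] (negative z clips to 0,
values above 2 to 2). Row order is an indirect stable sort by (cluster id,
first-peak time); rows without peaks sort last within their cluster in input
order. The numeric matrix is exported alongside the PNG so nothing downstream
ever parses pixels. Rendering is a pure function of its inputs.

## Flow and wave-speed analysis

The signal channel is binarized at mean + 0.5 SD over all pixels and frames
before tracking, to limit bleed-through of tissue motion. Signal motion is
summarized motion-sensing-superpixel style: a regular grid of seeds (default
200) advected per frame pair by the mean dense optical flow inside each
seed's tile restricted to the mask; the mean temporal flow map averages each
seed's displacement over frames where its tile held signal. Regular-grid
seeds (rather than content-adaptive superpixels) keep the method
deterministic and adequate at this scale. Two dense-flow backends:
iterative Lucas–Kanade (default) and TV-L1 (the robust choice for the large
displacements of epiblast waves), both from scikit-image.

Embryos are aligned by rotating the first principal axis of the cell
centroids vertical, with the 180° alternative chosen to put the mean ExE
centroid on top; a near-isotropic centroid cloud (eigenvalue ratio < 1.05) is
an error, while collinear clouds are fine.

Wave speed is the least-squares slope of front position against time. The
front is localized per frame with sub-pixel precision: profile averaged
across the perpendicular axis, furthest threshold crossing linearly
interpolated. Frames where the front has saturated at the far cell boundary
are excluded from the regression (they flatten the slope and bias speed low),
as are frames before signal onset. The intracellular benchmark (40-µm cell,
0.5-µm pixels, 0.5-s frames) recovers generated speeds across 2–20 µm/s
within a few percent. The exact procedure behind the reported in-vivo
epiblast speed is not fully specified upstream; the front-regression
definition here is the package's documented operationalization.

## Inhibitor experiments and statistics

Transient counts per embryo are summed over cells from 2-min, 10-s-interval
records (13 frames). The deterministic detector is the default counter at
this length — the CNN's 35-sample window would be mostly reflection padding —
with the CNN available explicitly. Group comparisons are one-way ANOVA
followed by all-pairs Tukey HSD (statsmodels); identical groups short-circuit
to F = 0, p = 1. DVE migration is scored on the reporter-domain centroid
track in the oriented embryo frame: migrated if the final angular
displacement from the distal pole (−y axis) is ≥ 30° (boundary inclusive).
The real experiments were scored by eye; the angular criterion is a
documented stand-in validated only on synthetic tracks, and condition-level
summaries are computed from outcome counts.

## Problem sizes used in validation

The shipped benchmarks run at desk scale, chosen to estimate each quantity
with comfortable statistical margin: 500 single-event traces for duration
recovery; 60 training / 30–60 held-out traces for the detector benchmarks;
252 cells × 14 embryos × 10 seeds for cluster recovery; 500 synthetic
embryos for the inhibitor means; 1,000 replications for the ANOVA type-I
calibration; 1,000 white-noise traces for the false-positive null.

## Known limitations

- Static ROIs: a moving cell smears its trace; no motion correction.
- The CNN does not transfer across frame intervals without retraining.
- Difference-based noise estimation is unstable below ~20 frames; very short
  records are best served by the deterministic detector with explicit
  parameters.
- Durations carry the +0…+2-frame discretization bias of the outer
  half-height convention; at 5-s frames a 20-s transient reads ~23 s on
  average.
- At the default operating point (z > 3) roughly 5 % of event-free,
  drift-bearing 121-frame traces still yield one marginal call, so the
  active-cell percentage of a nearly quiescent tissue reads several points
  above its true event fraction. Raising the threshold buys specificity at
  the cost of the marginal true events that sit at z ≈ 3–4 at SNR 5.
- HDBSCAN results depend on `min_cluster_size`/`min_samples`; the defaults
  target the reference cohort scale and should be revisited for datasets an
  order of magnitude smaller or larger.
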