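# embryocal

Quantification of cytosolic calcium dynamics in live-imaged early
post-implantation mouse embryos.

At embryonic day 5.5 the mouse egg cylinder shows widespread, tissue-specific
Ca²⁺ transients: frequent oscillations in the visceral endoderm (emVE, exVE)
and extraembryonic ectoderm (ExE), rare but expansive multicellular waves in
the epiblast. `embryocal` is a reusable implementation of the full
quantification pipeline for such recordings — single optical sections of a
GCaMP6f-type reporter imaged every 5 s for 10 min with per-cell ROI labels —
aimed at developmental biologists and image analysts who want the same
measurements on their own data, with every stage testable against synthetic
ground truth.

Stages (each a module, composable or scriptable):

| stage | what it does |
|---|---|
| `synthdata` | synthetic embryos, traces, wave movies and inhibitor experiments with ground truth |
| `traceio` | TIFF/label/CSV I/O; per-cell mean-intensity trace extraction |
| `detrend` | asymmetric-least-squares baseline removal (`ALSDetrender`) |
| `peakdetect` | transient peak calls: 1-D CNN classifier (`CNNPeakDetector`) + deterministic reference detector |
| `peakmetrics` | per-peak half-height durations; per-cell and per-tissue summaries |
| `clustering` | cross-correlation similarity + HDBSCAN grouping of trace dynamics (`TraceClusterer`) |
| `kymograph` | normalized, cluster-sorted kymograph rendering |
| `flowmotion` | signal binarization, superpixel optical-flow tracking, embryo orientation, wave-speed estimation |
| `experiments` | inhibitor-experiment counting, DVE-migration scoring, ANOVA + Tukey HSD |

## The core methods

**De-trending.** The baseline z of a raw trace y minimizes
Σᵢ wᵢ(yᵢ−zᵢ)² + λ Σᵢ(Δ²zᵢ)² with asymmetric weights wᵢ = p when yᵢ > zᵢ and
1−p otherwise (defaults λ = 10⁵, p = 0.01), iterated to a fixed point: slow
drifts are absorbed, ~20-s transients pass through.

**Peak detection.** A small 1-D CNN maps each symmetric window of N = 35
samples of the de-trended trace to P(peak at window centre); training labels
are "idealized traces", binary vectors nonzero only at annotated peak frames.
A deterministic robust-z reference detector stands in for the manual
annotator, serving as label source and as the oracle in equivalence tests.

**Metrics.** Peak duration is the half-height width at native sampling (last
frame below half on the rise to first frame below half on the fall);
the oscillation period is the mean peak-to-peak distance (cells with < 2
peaks have no period); tissue summaries report the active-cell percentage.

**Clustering.** Pairwise similarity = largest positive value of the
normalized signal cross-correlation over all lags; HDBSCAN on distance 1 − s.
The global mode pools all embryos (traces z-scored per embryo) and keeps the
outlier class as an extra cluster; cluster ids ascend with mean transient
count, so cluster 0 is always the most quiescent.

**Waves.** The signal is thresholded at mean + 0.5 SD; wave-front speed is
the regression slope of sub-pixel front position on time; superpixel seeds
advected by dense optical flow (Lucas–Kanade or TV-L1) summarize propagation
direction.

## Worked example

Simulate a 14-embryo cohort shaped like the reference dataset (1,126 cells:
323 epiblast, 430 ExE, 205 emVE, 168 exVE), de-trend, detect transients, and
summarize per tissue:

```python
import numpy as np, pandas as pd
from embryocal.synthdata import SimConfig, make_cohort_layouts, simulate_embryo_dataset
from embryocal.detrend import detrend_trace, BaselineParams
from embryocal.peakdetect import oracle_detect
from embryocal.peakmetrics import metrics_from_calls
from embryocal.traceio import traces_to_wide

layouts = make_cohort_layouts(14)
traces = pd.concat(
    [simulate_embryo_dataset(SimConfig(seed=100 + i), lay)[0]
     for i, lay in enumerate(layouts)],
    ignore_index=True,
)
meta, mat = traces_to_wide(traces)
det = np.vstack([detrend_trace(r, BaselineParams()) for r in mat])
calls = [np.array([c.frame for c in oracle_detect(r)], int) for r in det]
cells, tissues = metrics_from_calls(det, meta, calls)
print(tissues[["tissue", "n_cells", "n_active", "percent_active", "mean_n_peaks"]]
      .to_string(index=False))
```

prints

```
  tissue  n_cells  n_active  percent_active  mean_n_peaks
epiblast      323        64            19.8      0.216718
     ExE      430       188            43.7      0.572093
    emVE      205        93            45.4      0.614634
    exVE      168        98            58.3      0.875000
```

Reading this: the generator's tissue rates are calibrated so that the *true*
active fractions follow 1 − e^(−rate) (≈ 10 / 38 / 41 / 56 % here), and the
detected fractions reproduce the tissue ordering — epiblast quiescent, exVE
most active. The detected percentages sit a few points above the true event
fractions because, at the default detection threshold, ~5 % of event-free
traces still produce one marginal call; the effect is most visible in the
nearly silent epiblast. `mean_n_peaks` is the mean number of detected
transients per cell in 10 min.

There is also a CLI covering each stage end to end:

```bash
embryocal simulate --what embryo --seed 3 --out run/
embryocal detrend --traces run/traces.csv --out run/detrended.csv
embryocal detect  --traces run/detrended.csv --out run/peaks.csv
embryocal metrics --traces run/detrended.csv --peaks run/peaks.csv --out run/m
embryocal run --seed 5 --out run/full   # whole pipeline, deterministic per seed
```

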