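# Methods

## Scope

`colonypat` quantifies the morphological state of pluripotent colony
cultures from phase-contrast images by taught-library tile
classification, and builds four analyses on top of the resulting
coverage metrics: time-series monitoring with statistical separation,
imaging-sample-size design, per-colony size/response analysis with
diameter triggers, and morphology-to-cell-count regression. All
development and validation runs on a synthetic scene generator with
exact ground truth; nothing in the package depends on any particular
imaging hardware.

## Synthetic scenes

A colony is modelled as three concentric circular zones on a uniform
background: central core (dark, dense), core periphery (intermediate)
and edge cells (light, sparse). Real colonies are irregular; circles
carry the same class structure while giving closed-form disc/annulus
areas to test against. Zone widths are fractions of the colony radius,
default (0.55, 0.30, 0.15) for core/periphery/edge — chosen so that the
core, as an area fraction, is ≈30 % of the colony and a fully retained
core caps edge conversion near 70 % of colony area.

Each class draws its pixels from a stationary texture: a Gaussian noise
field smoothed at a class-specific granularity scale, rescaled to a
class mean and sd (grey levels in [0, 1]), plus additive pixel noise
(sd 0.01). Defaults (mean / sd / granularity px): background
0.62/0.020/1.0, core 0.30/0.090/1.5, periphery 0.44/0.055/2.5, edge
0.54/0.035/4.0. These make the classes separable by texture yet
overlapping in raw intensity; they are not calibrated to any specific
instrument. There is no phase-contrast optics model (no halo or
shade-off) and no colony merging or cell-level rendering, so classifier
accuracies measured here are an upper bound on what identical settings
would achieve on real images — the pipeline's statistical machinery, not
the absolute accuracy, is what transfers.

Kinetics: colony diameter grows linearly (default 4 µm/h) until the
differentiation stimulus; afterwards an edge front advances inward at
`edge_conversion_rate_per_h` (default 0.03, as a fraction of colony
radius per hour), converting periphery before core (outside-in, matching
the peripheral-outgrowth picture). Colonies whose diameter exceeds the
core-retention threshold (default 400 µm) never lose their central core;
smaller colonies convert completely. Pixel calibration defaults to
2.0 µm/px (a low-power objective); it is a free parameter. The imaging
interval defaults to 0.5 h.

Cell-count tables are generated as
count = β₀ + β_core·core% + β_periphery·periphery% + β_edge·edge% + ε,
ε ~ N(0, σ). Defaults β₀ = 2×10⁵, β = (3×10⁴, 1.8×10⁴, 4×10³) cells per
coverage point encode the density ordering core > periphery > edge;
σ = 5×10⁴ (≈5 % of a typical count) keeps every coefficient identifiable
at n = 200 with relative standard errors under ~10 %, which is what
"moderate noise" is taken to mean here.

## Taught libraries and classification

Patches are 64×64, quantised to the 16-bit grid on construction so PNG
round trips are exact. The descriptor (31 dims) concatenates mean, sd,
skewness; a 16-bin intensity histogram; gradient-magnitude mean and sd;
and a rotation-invariant uniform LBP histogram (P = 8, R = 1, computed
on the 16-bit image, 1-px border dropped where the circular
neighbourhood is truncated). Features are z-scored with centre/scale
pooled over all classes (scale floored at 10⁻⁸) so inter-class distances
are comparable. The commercial systems this emulates do not disclose
their recognition method; this descriptor set was fixed once for
intensity + granularity discrimination, which is how the three zones
differ.

Teaching uses scenes with one large colony whose zone widths are widened
to (0.40, 0.30, 0.30) so that every annulus admits 64-px windows of
≥0.9 mask purity; patches are harvested without replacement over all
eligible window positions, split across two independently textured
scenes. Default library size is 200 patches/class — the practical
trade-off between precision and teaching time; held-out accuracy is
already saturated there under default textures.

Classification tiles the image into non-overlapping 64×64 squares
(partial border tiles are excluded; the analysed-area fraction is
reported so coverages stay comparable). Each tile takes the majority
class of its k = 5 nearest library patches by Euclidean distance on
z-scored features; ties break by smaller mean distance among tied
classes, then by the fixed order background < core < periphery < edge,
so results are deterministic. The match score is the mean distance of
the k neighbours. No spatial smoothing is applied to the label map.
"Edge coverage" defaults to edge tiles / all analysed tiles; a flag
switches the denominator to non-background tiles (used for per-run
response curves, where the colony, not the field, is the natural basis).

## Precision and separation statistics

SEM uses the n−1 sample sd; the 95 % CI half-width is 1.96·SEM. The
normal multiplier (not Student-t) is used throughout: at the sample
sizes of interest (tens of images) the difference is negligible and z
keeps the sample-size inversion closed-form,
n = max(2, ⌈(1.96 σ/h)²⌉). The design guarantee is on the estimate:
at the returned n the sample mean lands within ±h of the truth ≥95 % of
the time (verified by simulation). SEM-vs-n curves subsample the image
pool without replacement — mirroring resampling of a finite image set —
averaging the subsample SEM over 200 resamples per n.

Separation between two monitored arms is a Welch (unequal-variance)
t-test per shared timepoint; the separation time is the earliest
timepoint where p ≤ α (default 0.05) holds for 3 consecutive frames
(1.5 h at the default interval). The sustain window exists because real
monitoring shows transient artifacts (e.g. refocusing after feeds) that
should not trigger; it also suppresses single-frame false positives at
the 5 % rate a raw scan would admit. When both samples are constant the
p-value is defined as 1 if equal, 0 otherwise.

## Colony analysis

Colonies are 4-connected components of non-background tiles; components
under 2 tiles are discarded as debris. Area is tile count × (64·µm/px)²
and size the equivalent circular diameter 2√(A/π) — tile-resolution by
design, matching the granularity of the classification the maps come
from. Tracking is greedy nearest-centroid linking with a 2-tile maximum
displacement, ties broken by distance then id, making it invariant to
input ordering; unmatched colonies start new tracks and gaps end tracks.
Per-colony composition uses colony tiles as denominator.

Size-response takes each track's diameter at the stimulus time and its
edge fraction at the horizon, reporting Pearson r and an OLS slope.
Diameter triggers fire at the first frame whose measured mean diameter
reaches the threshold; because diameters are tile-quantised, small-
colony triggers fire at the measurement granularity (a ~2×2-tile colony
reads 289 µm until it claims a fifth tile), which delays a 300 µm
trigger relative to the true crossing — the behaviour a real
tile-resolution PAT would show.

## Count regression and flask statistics

Fits are plain OLS with intercept (no weighting or robustness). The
single-predictor model uses total non-background coverage, the natural
confluence analogue; since that predictor is the sum of the three
per-class coverages, the three-predictor model nests it and its R² is
never lower. Rank-deficient designs are rejected with the collinear
predictors named. Prediction intervals are standard OLS 95 % intervals,
with extrapolation outside the training range flagged. Flask statistics
report CV = s/mean and the 95 % half-width for predicting batch yield
from m sacrificed units as 1.96·CV/√m (% of mean), for m = 1..n.

## Standard study conditions (`scenarios`)

The analyses run on fixed synthetic populations, scaled for a desktop
run:

- **Differentiation course** (coverage validation): 20 fields of
  1280×1280 px, four colonies of 250–700 µm each, imaged at stages
  stratified over 0–28.5 h of conversion. Stratification guarantees the
  edge-coverage dynamic range a monitoring application actually sees.
- **Random fields of view**: 256×256 px, one colony of 120–260 µm at a
  random position — the unit of random-position sampling. Precision
  pools use 400 such fields; separation monitoring samples 36 fresh
  fields per arm per timepoint (24 frames at 0.5 h, stimulus at 3 h), so
  per-image values are independent across frames. Monitoring series are
  mask-derived (exact geometry), isolating the sampling statistics from
  classifier jitter.
- **Size-response population**: nine colonies, 260–760 µm evenly spaced
  across the 400 µm retention threshold, followed for 30 h at 3 h
  intervals through the full classify/segment/track pipeline. The five
  largest sit at the grid corners and centre so neighbouring colonies
  always keep ≥2 background tiles between them (tile-resolution
  segmentation cannot merge them), and the smallest (260 µm ≈ 4 tiles)
  stays above the debris floor.
- **Triggered runs**: four growing colonies starting just below the
  trigger threshold (300 or 750 µm); the stimulus is applied when the
  measured mean diameter crosses it, and the edge response (colony-area
  basis) is followed for 16 h.

## Numerical and degenerate-input choices

- Constant patches: sd-dependent features (sd, skewness, gradient) are
  0; histograms remain defined.
- Full conversion collapses the core/periphery radii to zero; the whole
  colony disc, centre pixel included, is then edge.
- Zero-variance inputs: size-response with identical sizes reports the
  correlation as absent with a warning; regression on a constant
  predictor raises.
- All randomness flows through explicit integer seeds via
  `numpy.random.SeedSequence`; identical (spec, seed) inputs give
  bit-identical images, label maps and tables.

## Known limitations

- Tile-resolution boundaries: coverage carries a rim-quantisation error
  of roughly 1–2 percentage points per class at the default field sizes,
  and colonies near the retention threshold have cores smaller than one
  tile, which the classifier cannot resolve — their measured conversion
  saturates at 100 % even though a small core remains.
- The texture model contains no illumination gradients, debris, or
  optical artifacts, and colonies are circular and non-overlapping;
  passing tests demonstrate the correctness of the pipeline's
  statistics and bookkeeping on data satisfying its assumptions, not
  classifier performance on real cultures.
- Greedy tracking has no gap-closing or merge/split handling.
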