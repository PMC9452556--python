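# Methods

This note documents the models and procedures implemented in
`astrocircuit`, the defaults they use, and what the synthetic-data
generator does and does not emulate.

## Trace model and event process

Each ROI fluorescence trace is modelled as

```
F(t) = F_b + m·t − Σ_k A·g(t − t_k) + ε(t),
g(u) = (1 − e^(−u/τ_r))·e^(−u/τ_d) / g_max,   u ≥ 0
```

with baseline `F_b` (default 100 a.u.), bleaching slope `m ≤ 0`
(−0.02 a.u./s, ≈7% over a 6-min recording), transient amplitude `A`
expressed as a fraction of baseline (0.15) and applied as a **decrease**
(the green indicator dims when it binds Ca²⁺), rise time τ_r = 1.5 s,
decay time τ_d = 4 s, and white Gaussian noise ε with σ = 0.002·F_b.
The kernel is normalised so the planted peak depth is exactly `A`; the
peak occurs `τ_r·ln(1 + τ_d/τ_r)` ≈ 1.7 s after onset. Ground truth
records both onsets and peak times; the peak times are what an event
detector is expected to localise.

Event onsets follow a renewal process per rate epoch: a dead time of
8 s followed by an exponential wait, started in renewal equilibrium so
the expected count in a window is exactly `rate × duration`. The dead
time encodes that two transients closer than a transient width are one
fluorescence excursion, not two; a pure Poisson process would place
events closer than the 3-s peak-separation rule can resolve, making any
detector look worse than it is. The rate steps from 0.5 events/min
(basal) to 1.25 events/min at the stimulation onset (ratio 2.5). The
basal and stimulated epochs restart independently, so the dead time is
guaranteed within an epoch but not across the onset boundary.

Two generator-level calibrations follow from the analysis method's own
operating assumptions rather than from any reported measurement:

- **Noise level.** The event threshold is clamped from below at 0.004
  specifically to protect silent traces; that only matters if
  noise-driven thresholds (≈3.4σ) fall at or below 0.004, i.e.
  σ ≲ 0.1–0.2% of baseline. The default σ = 0.2% puts silent-trace
  thresholds at the clamp.
- **Transient occupancy.** The percentile baseline (below) tolerates
  downward excursions only while they occupy well under ~20% of each
  segment. Rates and transient duration are chosen to respect that
  (stimulated occupancy ≈ 20%); denser regimes visibly bias the
  baseline and the |ΔF|/F₀ rectification then manufactures spurious
  peaks between events.

## Per-ROI processing chain

1. **Trim**: the first 5 s are removed (non-linear early bleaching).
2. **Low-pass**: zero-phase Chebyshev type II, default order 2,
   stopband edge 0.75×Nyquist, 20 dB per pass (40 dB effective after
   forward–backward application). The filter is deliberately mild: at
   1 Hz sampling an aggressive low-pass delays the apparent peak of an
   asymmetric transient by several seconds and pre-rings at the onset;
   after rectification the ring lobe satisfies all three detection
   rules and becomes a systematic false positive ~5 s before each real
   event. Order, cutoff and attenuation are all configurable.
3. **Baseline F₀**: the filtered trace is cut into 30-s segments; the
   80th percentile of each segment is taken and a least-squares line
   through the (segment-centre, percentile) points is evaluated at
   every frame. For a monotone segment the 80th percentile sits a fixed
   offset above the segment centre, so the fitted line is parallel to a
   drifting trace, which is what |ΔF|/F₀ needs.
4. **Normalization**: `|filtered − F₀| / F₀` per frame (absolute value
   because the indicator is negative-going). A non-positive baseline
   anywhere is an error.
5. **Event threshold**: `th = 3/(n−1)·Σ|x_i − x_{i−1}|`, clamped from
   below at 0.004. The statistic scales with both noise and event
   density, and is scale-covariant before the clamp.
6. **Detection**: local maxima that are (a) strictly above `th`,
   (b) of topographic prominence ≥ 0.2·`th`, and (c) at least 3 s from
   any retained peak. The rules are applied in that order; conflicts
   under (c) are resolved greedily by descending amplitude with
   earlier-time tie-break, which is deterministic. Peak time and
   amplitude are read off the normalized signal.

Internally everything is indexed in frames; second-valued parameters
convert via the frame rate with round-half-up.

## Activity summaries

Per slice and analysis window (default 3 min before and 3 min after the
stimulation onset): the fraction of responding ROIs (a ROI responds iff
it has ≥1 detected event in the window), mean event frequency (min⁻¹)
and mean amplitude, plus frequency in 20-s bins (trailing partial bins
dropped). `change_from_basal` divides each stimulated-window metric by
its basal counterpart for the same slice; a zero basal denominator is
reported as missing with a warning. The slice-level frequency ratio
also carries a log-normal 95% interval treating pooled window counts as
Poisson — conservative here, because the dead time under-disperses the
counts.

## Image scenes

A scene is a registered basal/stimulated image pair plus no-virus
controls, rendered at 10 µm source pixels on a 60×80 grid of 50 µm
cells. Geometry is parametric: an elliptical nucleus with a concentric
elliptical core (55% linear scale) and the shell as the remainder;
registration is perfect by construction. Images compose additively:

- **autofluorescence**: a broad Gaussian field (base 2, amplitude 3 a.u.)
  plus a uniform background (5 a.u.), present in every image;
- **afferent reporter**: sharp-edged (logistic, 2 px edge) circular
  territories, one per subregion, amplitude 6 a.u.;
- **activation (astrocyte red)**: a basal photoconversion gradient
  (broad Gaussian, amplitude 2) in both members, plus stimulated
  territories overlapping the afferent ones; the shell territory's
  amplitude compensates the weaker basal gradient there so both sit at a
  comparable level;
- **noise**: white Gaussian, σ = 0.5 a.u. per source pixel (0.1 a.u.
  per grid cell after 5×5 averaging).

Blob fields are truncated to exactly zero beyond 10 edge-widths so
noise-free exactness checks are meaningful. The planted binary regions
are the half-maximum contours, coarsened to the grid with the same
≥50%-coverage rule the partition uses.

## Grid maps (partition in regular quadrants)

Registered images are divided into 50 µm × 50 µm cells, each summarised
by the mean of its source pixels (trailing partial rows/columns are
dropped). Masks are coarsened with a ≥50% area rule. Per cell,

```
G[i,j] = (mean fluorescence − R[i,j]) / F₀
```

where `R` is the per-cell mean over control slices and `F₀` is the mean
raw grid value in a background ROI outside the nucleus. The background
is computed on the grid-binned image (consistent units with the cell
values; the alternative — raw-pixel background — differs only by the
partition's averaging). Basal/stimulated pairs are then divided by the
basal in-nucleus mean, pinning it to exactly 1 so stimulated values read
as change from basal; this is a global scalar and preserves every
cell-to-cell ratio. Cells outside the nucleus are explicit missing
values, excluded from all means. Display truncation is a rendering
option only; analysis always uses untruncated values.

Quantification lines are stored as explicit polylines of grid cells
(they are figure-defined anatomy in the original workflow); the built-in
default walks the row through each subregion's centroid, truncated at 25
cells (core) / 44 cells (shell).

## Activation masks and spatial analytics

The activation threshold of a map is obtained by k-means on the
one-dimensional distribution of in-nucleus cell values — k = 5 for
afferent channels, k = 6 for photoconverted-red astrocyte channels —
with the threshold defined as the smallest value assigned to the
highest-centroid cluster, so `value ≥ threshold` reproduces that cluster
exactly. In one dimension the k-means objective is solved **exactly**
by dynamic programming over contiguous partitions of the sorted values
(O(k·n²) with prefix sums); this removes restart stochasticity entirely
(Lloyd-style restarts were measured to miss the global optimum on ~3% of
generic inputs). Ties in the DP are broken toward the smaller boundary
index.

Mask analytics: overlap is the logical AND of the afferent and astrocyte
masks; areas are percentages of the region's cell count (whole nucleus,
or the subregion for subregion-resolved entries; cells in the nucleus
but in neither subregion contribute to whole-nucleus figures only). The
bivariate similarity index is (overlap/astrocyte-area,
overlap/afferent-area), both in [0,1]; zero-area denominators are
reported as missing. Between-subregion comparison of the bivariate
points uses one-way MANOVA with the sequential dimensionality test:
eigenvalues of W⁻¹B, Wilks' Λ over the trailing eigenvalues, Bartlett's
χ² approximation, and `d` = the smallest dimension not rejected at
α = 0.05 (0 means indistinguishable). The reported statistic/p-value are
for the d = 0 test; the unit tests cross-check the p-value against
statsmodels' Wilks F approximation.

Pixel-by-pixel Pearson correlation pairs cells valid in both maps; with
thresholding enabled, each map is thresholded by its own activation
threshold and only cells surviving in **both** maps are paired (a flag
disables this). No spatial-autocorrelation correction is applied to the
p-value. Overlap probability maps are per-cell means of binary overlap
masks across slices — exact rational fractions count/n.

## Determinism and numerics

All randomness flows from one top-level seed, expanded per stage and per
slice via `SeedSequence` (child seeds kept below 2³¹). The k-means
threshold is exact and needs no seed. CSV output uses 9 significant
digits; grids are 32-bit float TIFF. Reruns with identical configuration
produce byte-identical CSV/JSON outputs (the run record, which carries
wall-clock timings, is written separately).

## Problem sizes used in the test suite

Detector–oracle equivalence uses 1,000 random 200-sample traces;
detection performance 200 simulated ROIs; rate-ratio coverage 200
simulated slices of 50+50 ROIs over 3+3 min; mask recovery 20 seeded
scenes; correlation nulls 500 map pairs of 1,000 cells. Detection
performance is scored against planted events whose peak lies in the
evaluable range (after the trim, before the last frame); events peaking
inside the trimmed head or beyond the recording cannot be found by any
method.

## What the generator does not emulate

No optics: no point-spread function, no depth attenuation, no mosaic
stitching artifacts. No registration error (images are aligned by
construction; the real workflow registers slices elastically before
analysis). No photoconversion chemistry — the "red" channel is a static
planted field, not an integral of simulated Ca²⁺ activity. Anatomy is an
ellipse, not an atlas outline. Inter-event statistics of real astrocytes
are unknown; the dead-time renewal process is a stand-in, not a claim.
Consequently, passing tests demonstrate that the analysis chain recovers
what it is defined to recover under controlled conditions — they do not
validate biological conclusions drawn from real slices.

## Known limitations

- The percentile baseline biases low when transients occupy more than
  ~20% of a segment; very active ROIs inflate |ΔF|/F₀ between events.
- The event threshold grows with event density (it is computed from the
  same signal it gates), so amplitude-to-threshold margins shrink on
  busy traces.
- The dead time is not enforced across the basal/stimulated boundary.
- Boundary grid cells mix in/out-of-mask source pixels under the ≥50%
  rule; planted-region recovery is limited by this discretisation
  (Jaccard ≈ 0.83 for territories of ~10-cell radius).
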