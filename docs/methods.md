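# Methods

This note records how `phenoplate` measures, corrects and tests colony
fitness, which knobs matter, and where the methods' assumptions end.

## Image model and segmentation

A plate photograph is loaded as intensities in [0, 1] (any bit depth).
Transmission scans may have colonies darker or lighter than the agar; the
orientation is auto-detected by a global Otsu split (the foreground is
assumed to be the minority phase) and can be forced with `invert`.

Detection runs in four steps: adaptive mean thresholding over square blocks
(block size defaults to roughly one lattice pitch, i.e. about twice the
expected colony diameter; a pixel must exceed its local mean by 0.05),
morphological opening with a radius-1 disk, hole filling, and removal of
objects below a minimum area (1% of the pitch cell, at least 4 px). Each
surviving object is then trimmed to its half-maximum contour — the pixel set
above (background median + object peak)/2. Local mean thresholding admits
anti-aliased edge pixels far below half coverage and inflates areas by
~5–6%; the half-max cut restores the convention under which a rendered disk
of radius r has area ≈ πr² (measured error ≤ 1% at r = 20 px, ≤ 4% at
r = 8 px).

Grid assignment fits an evenly spaced lattice per axis: centroids are
clustered along the axis, consecutive cluster gaps are snapped to integer
multiples of the smallest gap, and origin/pitch are refined by least
squares. Objects farther than half a pitch from every node are discarded;
when two objects compete for a node the larger wins (logged). The `scale`
parameter (e.g. 0.1 for large scans) downsamples only the detection step;
masks are upsampled and all geometry is reported in original pixels.
Half-scale processing changes mean colony area by ~1% on synthetic plates.

Per-colony outputs: area, perimeter, circularity 4πA/P² (capped at 1.2 to
absorb discretisation overshoot on small objects), centroid, and intensity =
Σ(pixel − background median over off-colony pixels), clipped at 0 — a
thickness-sensitive size proxy.

**Redness.** Phloxine B stains dead cells, so redder colonies contain more
dead cells. Segmentation runs on a colour-enhanced image (each channel
stretched to span [0, 1]); the score itself is the mean chromaticity
R/(R+G+B) over the colony footprint computed on the *original* pixels.
Chromaticity is invariant to exposure and uniform illumination scaling,
which suits reflective scanning; a neutral grey colony scores exactly 1/3.
Footprints are eroded by one pixel for the average so that colour-blended
edge pixels do not dilute the score. We deliberately do not background-
subtract the channels before the ratio: with a bright background that would
floor colony channels to zero and destroy the score's meaning.

**Timecourse.** Positions are detected in the last image only; that fixed
mask is applied to every frame, with a per-frame background median
(subtracting a per-frame global background makes the series invariant to
uniform illumination drift, verified to 10⁻¹³ relative). Whether a local
per-colony background would be preferable is an open question; the global
median is robust to the changing colony density across a series.

## Growth parameters

`fit_max_slope` fits ordinary least squares in every window of `fitrange`
consecutive timepoints and reports the largest slope, the mean time of the
winning window, its R², the initial/final levels (means of the first/last
window), and the lag — where the winning regression line crosses the
initial level y₀, clipped at zero and undefined when the slope is not
positive or the crossing precedes the first timepoint by more than one
sampling interval. Windows containing missing values are skipped, never
imputed. Constant series are flagged (`constant-series`) rather than fitted.

Defaults: `fitrange = 12` at 20-minute imaging (a 4-hour window). The
estimator is exact on linear data at any window size; on logistic curves the
window average flattens the inflection, biasing the slope low by an amount
that grows with window width (≤ 3% at a 0.5-hour window, ~4–5% at the
default on typical rates) — monotone in `fitrange`, so comparisons at a
fixed window remain valid. With 5% multiplicative noise at the default
schedule the median relative error of the maximum slope is ≈ 4% and rank
recovery across a 1536-curve panel is ρ ≥ 0.96. Slopes are fit on raw
values, not logarithms, matching the pixel-sum units of the timecourse
table.

## Reference-grid normalisation

Control colonies at known positions carry the plate's spatial trend. The
expected-size surface is built in two stages:

1. **Node smoothing.** Usable controls (positive, non-missing) are smoothed
   by a local quadratic regression over a 5×5 window of neighbouring grid
   nodes (a 2-D Savitzky–Golay filter of order 2). Each control is measured
   with the same noise as any colony; without smoothing that noise
   propagates into every nearby corrected value as a *shared* error, which
   shows up as a spurious positive neighbour-sum correlation (~0.2 at 5%
   noise on a 1536 plate with 96 controls). The quadratic fit damps the
   noise while reproducing constants, planes and quadratic surfaces exactly,
   including at truncated border windows.
2. **Interpolation.** When the controls form a complete regular sublattice
   (the designed layouts), bilinear interpolation with linear extrapolation
   beyond the outermost controls — exact for planar trends at every
   position, including the plate borders outside the control hull. With
   missing controls the surface falls back to piecewise-linear (Delaunay)
   interpolation inside the hull and nearest-control fill outside; excluded
   controls are flagged (`missing grid colony`). Fewer than three usable,
   non-collinear controls is an error; non-positive expectations are
   flagged as artefacts and the position comes out missing.

Corrected fitness is raw/expected; it is invariant to rescaling the whole
plate. With only 96 controls informing 1536 positions at 5% measurement
noise, the surface retains ~2% shared uncertainty; on plates whose
biological spread is comparable to that floor a small positive residual
neighbour correlation remains. On wild-isolate-like plates (fitness spread
σ ≈ 0.25) regional gradients dominate the raw readout (neighbour r ≥ 0.5)
and correction leaves |r| ≤ 0.1 without ever turning it significantly
negative — over-correction would make phenotypes look artificially extreme.

## Row/column median normalisation

Each value is divided by its row median, then by the recomputed column
median (order fixed, recorded in `normalisation_method`). The method
assumes the *majority of strains in every row and column are neutral* — the
knock-out-collection setting; with broad uniform effects the medians absorb
signal. Grid colonies are included in the medians (they are neutral by
design). Separable row×column effects are removed completely in one pass;
the operation is not exactly idempotent on general matrices (the column
step perturbs row medians), which is why the pipeline runs it once, after
grid correction when both are requested — the recommended remedy for the
secondary edge effect that grid correction can leave in the first inward
row/column. Zero medians raise an error; all-missing rows/columns propagate
missing values.

Zero-size colonies are set missing before any normalisation (failed
pinnings, not small colonies). Every value that normalisation turns missing
carries an explanatory `qc_flags` entry, so missingness is always traceable.

## Quality control

CV = sample sd / mean over the replicated grid controls; FUV =
var(controls)/var(all colonies) (sample variances, n−1). Both are invariant
to rescaling the plate. Defaults follow standard screen practice: colonies
with circularity < 0.85 or zero size are set missing; plates with control
CV > 0.2 or FUV > 1 are removed. Colony-level filtering runs before the
plate statistics. Plates without enough controls to compute CV/FUV are kept
and annotated, not silently dropped. The neighbour-sum diagnostic excludes
border positions rather than renormalising by neighbour count, keeping the
statistic comparable across plates.

## Differential fitness

Contrasts are built per strain either against the same strain in a control
condition (the recommended axis for condition-specific effects) or against
the pooled population of all other non-grid strains in the same condition.
The default test is Student's pooled two-sample t-test on corrected values:
screens typically run n = 3 replicate colonies, and at that size the pooled
test holds its nominal level (measured 4.9% at α = 0.05 on a fully null
simulated screen) while the Welch-Satterthwaite approximation is noticeably
conservative (~3.4%). Welch (`test="welch"`) is available for strongly
heteroscedastic contrasts, and Mann-Whitney (`test="ranksum"`) for
heavy-tailed data. Effect size is the ratio of medians
(condition/control) — robust and scale-free. Benjamini–Hochberg adjustment
is applied across all contrasts of one invocation by default (screen-wide
discovery framing; per-condition correction is available). Grid controls
are excluded from testing; contrasts with fewer than two replicates on
either side are reported with a reason instead of a p-value. The replicate
unit is the individual colony; values are not averaged before testing.

## Synthetic data: what it emulates, and what it does not

Colony values are multiplicative: base × strain effect × gradient ×
lognormal noise with a specified CV (sizes are positive; noise scales with
the mean). The spatial gradient is a separable cosine surface parameterised
by its peak-to-trough amplitude — a smooth stand-in for
temperature/moisture/nutrient fields. Growth curves are logistic with rates
drawn per position (default N(0.5, 0.1²) h⁻¹, K = 100, sampled every 20
minutes for 48 h → 145 points). Images render anti-aliased disks (radius ∝
√size) on a uniform background; RGB colonies mix a cream colour with a red
stain colour in proportion to the strain's dead-cell fraction, so redness
increases monotonically with death. An `axis_ratio` knob renders ellipses
for exercising the circularity filter. All generators are pure functions of
their seeded configuration.

Two named scenarios fix study conditions used across the test suite:
wild-isolate plates (effect spread σ = 0.25, gradient amplitude 0.8 — the
regime where regional effects dominate raw readouts) and knock-out screens
(spike-and-slab effects: 70% exactly neutral, 30% lognormal σ = 0.25 —
the neutral majority that row/column normalisation requires). Simulated
experiments write the same CSV dialects the CLI consumes, so the full
analyse → qc → interpret chain runs on generated files unmodified; strain
effects are recovered from a triplicate two-condition screen at Pearson
r ≥ 0.96.

The generator does not emulate: nutrient competition between neighbours
(colonies are independent given the gradient), within-colony texture or
spatial redness structure, lid reflections and other imaging artefacts,
non-separable or discontinuous plate effects, or batch-to-batch layout
errors. Passing tests therefore demonstrate correctness of the estimators
under smooth multiplicative spatial structure with independent
multiplicative noise — not robustness to every artefact of real scanners.

## Numerical choices and degenerate inputs

Sample statistics use n−1 denominators throughout. Circularity of a
zero-perimeter (single-pixel) object is 0. R² of a zero-variance window is
1 when residuals vanish, else 0. Pearson correlations involving constant
vectors are reported missing and flagged. Tie-breaks in grid assignment go
to the larger object. Degenerate two-group tests with zero pooled variance
give p = 1 when the means agree and p = 0 otherwise. BH adjustment skips
missing p-values and caps at 1. Problem sizes in the test suite (one plate
per format, 10-seed calibration batches, 100-run power studies) were chosen
to make each statistical property measurable with comfortable margin while
keeping the whole suite quick to run on a laptop.
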