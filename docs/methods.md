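# Methods

## Pipeline model

The pipeline treats a field as a set of disjoint cell areas, each
containing at most one centrosome pair. Detection operates only on the
γ-tubulin channel; the target channel is read only through the detected
masks. All coordinates are 0-based (row, column); all distances are
Euclidean in pixel units; connectivity is 8-neighbor everywhere
(components, floods, plateaus, watershed markers).

Stage order is fixed: segment → blur → per-cell peaks → expand → merge →
size-filter → measure → review → two-centrosome filter → statistics.
Review always precedes the eligibility filter; the two are
order-sensitive (a removed false positive can change a cell's centrosome
count from 3 to 2, or from 2 to 1).

### Detection details and tie-breaks

* Peak *locations* come from the blurred raster; peak brightness,
  expansion thresholds and fluorescence measurements use the unblurred
  raster. Blurring is for localization robustness; measuring on smoothed
  data would bias intensities toward neighbors. A `measure_on_blurred`
  flag inverts this for users who want the fully smoothed variant.
* The blur width is configurable (`blur_sigma`, default 2 px — wide enough
  to suppress single-pixel debris, narrow relative to the ≥ 6 px peak
  separation the peak finder enforces).
* Threshold boundaries follow the wording of the procedure exactly:
  expansion keeps pixels **≥** 0.70 × peak brightness; merging applies to
  peak distances **<** 10 px (10.0 px exactly is not merged); regions
  **<** 30 px are removed (30 px exactly survives).
* Region growing is connectivity-constrained (a flood from the peak), not
  a global threshold over the cell: an unconnected reading would swallow
  the sister centriole that the explicit merge step exists to handle.
* Brightness ties break toward the smallest (row, column) coordinate.
  An 8-connected plateau of equal-valued local maxima is one candidate at
  its lexicographically smallest pixel. A plateau at the cell's minimum
  value has no contrast at all and is flagged `low_contrast`; such
  candidates participate only when the cell offers nothing else, and the
  composed detector skips them (a flat cell has nothing to detect).
* Merging distance is measured peak-to-peak (for multi-peak regions, the
  minimum over cross pairs), with transitive closure.
* Per-cell processing is independent; results are identical to sequential
  execution by construction.

### Degenerate inputs

A cell whose γ channel is pure background is pathological for a
peak-relative threshold: 0.70 × (a background-level peak) falls below
most background pixels and the flood can cover much of the cell. With a
flat background the low-contrast rule above yields no regions. With
*noisy* background, a spurious second peak in a one-centrosome cell can
survive the size filter as a large dim region; this is exactly the class
of false positive the review stage removes (on synthetic data, the
emulated reviewer `annotations_from_truth` flags any region whose peaks
match no ground-truth spot within 4 px). The two-centrosome filter then
drops the cell if its true count was one.

## Segmentation

The external deep-learning segmenter is an optional backend carrying the
validated parameter block (`flow_threshold = 0`, `cellprob_threshold = 0`,
`tile_norm_blocksize = 0`, `diameter = 120`, `min_size = 20000`,
`niter = 2000`, `augment = true`); it is never silently substituted, and
its absence raises an explicit error. The package's own correctness
surface rests on two deterministic backends: a ground-truth pass-through
and a classical fallback (3-class multi-Otsu on log-intensities of a
smoothed cytoplasmic channel, lowest cut, DNA-seeded watershed split).
The log transform matters: the bright puncta dominate linear intensity
variance and pull any linear Otsu cut far above the cytoplasm level.
`diameter` and `min_size` scale with image resolution; the defaults
describe full-resolution data (cells ≈ 120 px across), while the synthetic
configurations use `diameter = 68`, `min_size = 800` for their ≈ 68-px
cells. Cells touching the field border are kept by default
(`exclude_border` available). Which channel feeds the segmenter is
user-specified; the synthetic default is the target channel, whose
cytoplasmic pool outlines the cell.

## Measurement

Centrosomal abundance is the arithmetic mean of the target channel over
the region's pixel set, with no background subtraction (an optional
per-cell median subtraction exists but is off by default, and nothing in
the validation depends on it). ROI means use pixel-center inclusion under
the even-odd rule, implemented on strict polygon interiors — centers
exactly on a boundary are excluded, a measure-zero convention for
free-hand outlines. Line profiles sample bilinearly at unit spacing from
start to end inclusive (⌈length⌉ + 1 samples); peak counting on profiles
uses prominence so that the centriole "double-hump" is a reproducible,
quantitative readout rather than a visual impression.

## Statistics

* **Random-intercept model.** Two centrosomes per cell are nested
  measurements; the model y_ij = β₀ + β₁·mitosis + u_i + ε_ij absorbs
  between-cell variation into u_i. REML is the default estimator (ML by
  flag); inference on β₁ is a two-sided Wald test. Boundary fits
  (σ_u → 0) are legitimate and flagged, not errors. The optimizer falls
  back from L-BFGS to derivative-free methods on tiny or boundary
  datasets where the Hessian is singular; non-convergence raises an error
  carrying the optimizer trace. Fits are validated two ways: closed-form
  collapse on balanced designs (β₁ must equal the difference of stage
  means) and a dense brute-force grid over (β₀, β₁, σ_u, σ_e) whose best
  log-likelihood the ML fit must match to 3 significant figures.
* **Mann–Whitney U.** Exact p by complete enumeration of the null
  permutation distribution (twice the smaller tail including the observed
  U, capped at 1) whenever the pooled sample is ≤ 12 with no ties;
  otherwise the normal approximation with midranks, tie correction and
  continuity correction. The method actually used is always reported.
* **Fold summary.** The interphase/mitotic ratio of stage means, with a
  percentile CI from a cluster bootstrap that resamples *cells* with
  replacement, stratified by stage — never individual centrosomes, which
  would pretend the nested measurements were independent.
* Two-sided tests throughout; every stochastic routine takes an explicit
  seed.

## Synthetic data: what it emulates, and what it does not

The generator renders what the pipeline assumes: non-overlapping disc
cells (rejection-sampled; an over-dense request fails with the attained
density), 1–2 isotropic Gaussian spots per cell truncated at 4σ and
evaluated analytically at sub-pixel centers, a stage-dependent target
amplitude (interphase amplitude divided by `stage_fold` in mitosis), a
stage-independent γ amplitude (a toggle can brighten mitotic spots),
nuclear blobs (two condensed bars for mitotic cells, rendered for
segmentation and visual sanity only — stage labels always come from the
truth table), perinuclear target-channel clutter, small bright γ debris,
and noise applied after compositing (Gaussian, or Poisson with the
composite as the rate).

Default parameters (chosen once as plausible for summed confocal stacks
of cultured cells, and so that the default scene exercises every filter
path):

| parameter | default | why |
|---|---|---|
| field, cells | 800×800 px, 24 cells | ≈ 15 % area fill, placement always succeeds |
| cell radius | 28–40 px | scaled-down analogue of ≈ 120 px cells |
| interphase centriole separation | 3–16 px | spans unresolvable (< 6), merged (< 10) and distinct pairs |
| mitotic pole separation | 20–40 px | spindle poles are well separated |
| spot σ | 4 px | puts the 0.70-threshold region at ≈ 37 px, above the 30 px size cut |
| γ amplitude | 400 | strong spots over background 8 |
| target amplitude (interphase) | 600; fold 2 | mitotic centrosomal signal halved |
| cytoplasm level (target) | 20 | outlines cells for segmentation; small vs spot signal |
| amplitude jitter | 10 % per cell, 5 % per spot | the per-cell factor creates the random-intercept structure |
| noise | Gaussian, σ = 6 | modest shot/read noise analogue |

Not emulated: 3D stacks (the analysis input is a 2D sum), PSF asymmetry,
photobleaching, stage drift, chromatic shift, overlapping or non-convex
cells, mitotic-pole brightness asymmetry (a parameter exists but defaults
off so the truth-table fold is exact). Passing tests therefore show that
the *algorithmic* chain — detection geometry, thresholds, merging,
measurement, filtering, statistics — is correct under the stated image
model; they cannot certify performance on real images with segmentation
errors, aggresomes, or out-of-focus structure, which is what the manual
review stage is for.

One deliberate compression effect: measured means include the additive
background and cytoplasm, so a true amplitude fold of 2 yields a measured
fold slightly below 2 (≈ 1.9 at the defaults). The simulation-recovery
checks accept 1.8–2.2.

## Problem sizes used in validation

The recovery checks run the full pipeline on a 1400×1400 px field with
120 cells (60 per stage; ≈ 80 cells survive the two-centrosome filter).
Calibration of the mixed model (type-I error in [0.01, 0.11] at α = 0.05;
95 % Wald coverage in [0.90, 0.99]) uses 200 record-level replicates of
25 cells per stage with two centrosomes each — rendering pixels would add
nothing to those purely statistical properties. Oracle-equivalence suites
(flood fill, exhaustive peak scan, union-find closure, Mann–Whitney
enumeration, likelihood grid) run on rasters ≤ 32×32 and pooled samples
≤ 8, where brute force is exact.

## Known limitations

* The two-centrosome eligibility rule also excludes cells with > 2
  detected centrosomes (amplification is out of scope for the stage
  comparison).
* Peak positions shift inward for spot pairs near the resolution limit of
  the blurred image (separation ≈ 2×effective σ), so truth separations in
  roughly the 9–11.5 px band may detect as merged single centrosomes; the
  eligibility filter makes this a dropout, not a bias.
* The Wald test has no small-sample df correction (no Satterthwaite);
  with very few cells its p-values are approximate — the calibration
  checks bound the damage at the sizes used here.
* `measure_roi_mean` requires simple polygons; self-intersecting
  free-hand outlines are rejected rather than repaired.
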