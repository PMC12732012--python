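# centroquant

Centrosome detection and fluorescence quantification for multi-channel
fluorescence microscopy fields (summed Z-stacks), with a synthetic-field
simulator and the statistics appropriate for nested per-cell measurements.

## The problem

The centrosome is the cell's main microtubule-organizing center, visible in
γ-tubulin immunofluorescence as one or two bright puncta per cell. Many
questions about centrosomal proteins reduce to: *how much of a target
protein sits at each centrosome, and how does that amount change between
interphase and mitosis?* Answering this from images requires segmenting
cells, finding the centrosomal puncta inside each cell, turning each
punctum into a measurement mask, and comparing measurements that are
*nested* — the two centrosomes of one cell are correlated observations,
not independent samples.

`centroquant` implements that pipeline for users who have multi-channel 2D
TIFFs (DNA / γ-tubulin / target protein) or who want to validate the method
end-to-end on simulated data with known ground truth.

## The method

Per segmented cell, in the γ-tubulin channel:

1. **Blur** the channel with a Gaussian (default σ = 2 px) to suppress
   debris and noise.
2. **Peak finding** — up to 2 local maxima per cell, greedily accepted in
   brightness order subject to a minimum pairwise distance of 6 px.
3. **Region growing** — the 8-connected flood, inside the cell mask, of
   pixels with intensity ≥ 0.70 × peak brightness.
4. **Merging** — peaks closer than 10 px (strict) are one centrosome; their
   regions are unioned.
5. **Size filter** — regions below 30 px are noise and removed.
6. **Measurement** — mean target-channel fluorescence over each region
   (no background subtraction).

After a review step (verdicts per labeled region, `cell-centrosome`), only
cells with exactly **two** detected centrosomes enter the stage comparison,
so every cell contributes a balanced pair. The comparison is a linear mixed
model with a per-cell random intercept,

y_ij = β₀ + β₁·1[stage_i = mitosis] + u_i + ε_ij,  u_i ~ N(0, σ_u²), ε_ij ~ N(0, σ_e²),

fitted by REML with a Wald test on β₁. ROI-level comparisons (manually
outlined cells, e.g. acetylated-tubulin levels in transfected vs control
cells) use the Mann–Whitney U-test, exact by enumeration for small
tie-free samples. The interphase/mitotic fold of mean centrosomal
fluorescence is summarized with a cluster bootstrap that resamples cells.

The bundled simulator renders fields of disc cells with 1–2 Gaussian
γ-tubulin spots each (interphase: one close centriole pair; mitosis: two
separated spindle poles), a target channel whose spot amplitude is halved
in mitosis by default (`stage_fold = 2`), nuclear DNA blobs, perinuclear
Golgi-like clutter, γ-channel debris, and Gaussian or Poisson noise — all
with a complete ground-truth table.

## Worked example

```bash
centroquant demo --seed 0 --out demo_run
```

prints (numbers from this exact command):

```
simulate: 24 cells (10 mitotic, 14 interphase)
segment: 24 cells (backend=ground_truth)
detect: 44 centrosome regions
review: 5 false positives removed, 39 records kept
filter[interphase]: 14 cells/19 peaks -> 5 cells/10 peaks
filter[mitosis]: 10 cells/20 peaks -> 10 cells/20 peaks
filter[total]: 24 cells/39 peaks -> 15 cells/30 peaks
stage fold (interphase/mitotic): 1.842 [95% CI 1.679, 2.003]
mixed model: beta1 = -242.5 (SE 19.5), p = 1.54e-35 (REML, 15 cells)
Mann-Whitney (interphase vs mitotic records): U = 200.0, p = 1.2e-05 (normal_approx)
```

Reading this: of 24 simulated cells, detection found 44 candidate regions;
review discarded 5 background pick-ups; the two-centrosome filter kept 15
cells (interphase cells whose centriole pair is unresolved or merged drop
out). The fold estimate ≈ 1.8 recovers the simulated two-fold reduction of
the target protein at mitotic centrosomes (the additive image background
compresses it slightly below 2), and the mixed model calls the mitosis
effect strongly negative. Identical seeds give byte-identical run
directories; each run writes a manifest with artifact hashes.

The same stages are available individually (`simulate`, `segment`,
`detect`, `measure`, `filter`, `stats mixed`, `stats mwu`, `profile`,
`run`) and as library functions (`centroquant.generate_field`,
`detect_centrosomes`, `measure_regions`, `select_two_centrosome_cells`,
`fit_random_intercept`, ...).

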