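# Methods

`fibroscreen` re-implements, as a tested pipeline on synthetic data, the two
computational arms of a high-throughput screen for inhibitors of
TGF-β1-driven fibroblast-to-myofibroblast differentiation: a high-content
imaging assay (per-cell feature extraction, control-trained SVM, per-well
percent effect) and a multiplexed impedance + MRM protein-quantification
assay, together with the dose–response, assay-quality and hit-triage
statistics that sit on top of both.

## The differentiation model

A single logistic dose rule links every synthetic readout. The expected
myofibroblast fraction of a stimulated well is

    f(d) = f_min + (f_max − f_min) · dʰ / (dʰ + EC50ʰ)

with EC50 = 0.07 ng/ml TGF-β1, Hill slope h = 1, f_min = 0 (an
unstimulated well is a pure fibroblast population) and f_max = 1. The same
midpoint governs the α-SMA protein induction in the MRM generator, so the
imaging and protein ground truths are mutually consistent; COL1A1 uses its
own midpoint of 0.05 ng/ml. Compound action multiplies the induced part of
every readout by the remaining-response factor of a three-parameter
logistic occupancy curve, `1 − e·c/(c + IC50)` at Hill slope 1 — at the
compound's true IC50 with full efficacy e = 1, exactly half the response
remains.

Well-to-well biological variability enters in two places: a multiplicative
log-normal jitter on the effective dose (CV 0.10, negligible at saturating
doses) and an additive Gaussian jitter on the realized fraction (SD 0.02,
truncated to [0, 1]). The second term dominates the control percent-effect
spread of a plate (~2 SD units on the 0–100 scale) and is what keeps the
simulated assay window in the Z′ ≈ 0.85–0.95 regime rather than at a
physically implausible 1.0.

## Image synthesis

Each well renders a four-channel 16-bit field (DAPI, α-SMA, fibronectin,
whole-cell; default 384×384 px, 120 cells) of elliptical cells placed on a
jittered grid. Myofibroblasts carry bright oriented α-SMA line segments
("stress fibers", Poisson-distributed count, mean 6) and punctate
fibronectin fibrils; fibroblasts carry diffuse low-contrast signal with at
most faint fibers. This creates the granularity/texture contrast the
classifier is meant to exploit without any attempt at optical realism (no
PSF model; a fixed σ = 0.8 px Gaussian stands in for blur).

Phenotype overlap is deliberate. Cell areas are log-normal (SD 0.35 in log
space) around class means 150 and 240 px², marker brightness per cell is
log-normal (SD 0.55) around class means that differ 3-fold (α-SMA 700 vs
2100 units), nucleus size is class-independent, and a per-well staining
factor (log-normal, SD 0.15) shifts all cells of a well coherently. Without
this overlap a linear classifier separates the classes perfectly and every
control well scores exactly 0 or 100 — a degenerate regime in which
cross-validated accuracy, Z′ and control SDs all collapse to their ideal
values and say nothing about the analysis code. The defaults were chosen so
the assay operates where screening assays of this type are reported to
operate: per-cell CV accuracy ≈ 0.98–0.99, control percent-effect SD ≈ 2,
Z′ ≈ 0.85–0.95.

Per-cell rendering rescales each blurred cell crop so that its in-mask mean
equals the configured class mean times the cell's brightness factor; the
configured class contrast is therefore directly recoverable by averaging
the rendered channel over ground-truth masks (a generator self-check).
Sensor noise is Gaussian with variance `read² + (cv·signal)²` (read noise
SD 20, cv 0.15), a standard shot-noise approximation.

Randomness is hierarchical: one master `SeedSequence` per plate is spawned
per well, so a well's field depends only on (seed, well position) and the
same seed reproduces bit-identical rasters and truth tables.

### What the generator does not emulate

Uneven illumination, focus drift, debris and segmentation-confounding
clumps, channel bleed-through, plate-edge effects, and any continuous
differentiation spectrum (cells are binary fibroblast/myofibroblast).
Passing tests therefore demonstrate that the analysis chain is correct and
well-calibrated on data satisfying its assumptions — not that it would
reach the same accuracy on real micrographs.

## Image analysis

Nuclei: Gaussian smoothing (σ = 2), Otsu threshold, removal of components
below 30 px², distance-transform maxima (5 px suppression) seeding a
watershed to split touching nuclei. Cells: seeded watershed on the inverted
smoothed whole-cell channel inside its Otsu foreground, one region per
nucleus. Cells touching the border are kept by default (configurable).

Features (~93 per cell, ≥ 40 per marker channel) on top-hat
background-corrected α-SMA and fibronectin channels (structuring element:
square of side 2·(2·max granularity scale)+1 = 33 px, separable and
therefore cheap; the radius follows the 2× largest-scale rule):

* intensity statistics (mean, SD, CV, quantiles, IQR, MAD, skewness,
  kurtosis, integrated, upper-decile mass, fraction above mean);
* granularity spectrum at opening radii {1, 2, 3, 4, 6, 8} px — each entry
  is the percentage of in-mask signal removed by the next opening of the
  previous opening result. Successive (rather than independent) openings
  guarantee a monotone sequence, hence nonnegative entries summing to
  ≤ 100 even on discrete grids;
* grey-level co-occurrence texture (contrast, correlation, homogeneity,
  dissimilarity, ASM, entropy) at offsets {1, 3} px averaged over four
  orientations on 32-level in-mask quantized intensities;
* sub-cellular structure (nucleus/cytoplasm and rim/interior means and
  ratios);
* shape (area, perimeter, eccentricity, solidity, form factor, axes,
  extent, nucleus area and ratio) and DAPI statistics.

Degenerate regions (single-pixel cells, constant intensity) produce defined
zero values rather than NaNs; every feature is finite by contract.

## Classification and percent effect

Training labels come from well roles, not per-cell ground truth: cells in
TGF-β1-stimulated negative-control wells are labelled myofibroblast, cells
in unstimulated positive-control wells fibroblast, exactly as an in-plate
control-anchored screen must operate. Because the stimulated controls are
~98.6% (not 100%) differentiated under the dose rule, this injects ~1.4%
label noise into one class, which is the main gap between measured CV
accuracy (~0.985) and 1.

The classifier is a linear SVM (squared-hinge, C = 1) on standardized
features, majority class subsampled to balance, with stratified 10-fold CV.
A linear kernel is the design choice because the assay exports per-feature
weights as a relevance ranking; on default plates α-SMA granularity or
co-occurrence features appear in the top ten.

Per-well aggregation: percent effect = 100·(f_neg − f_well)/(f_neg −
f_pos), anchored at the mean classified myofibroblast fractions of the two
control roles. Effects are not clipped to [0, 100] by default; a clipping
flag exists for reporting. Whether the original assay rescales the raw
fraction or an SVM-margin aggregate is not determinable from its
description; both the fraction and the effect are emitted.

## Impedance and MRM

Impedance traces follow cell-index convention: division by the value at
the compound-addition reference time (so the normalized trace is exactly 1
there; a subtraction mode exists as an option), then subtraction of the
identically normalized baseline-well mean, linearly resampled if grids
differ. Readouts are linear interpolations at t = 20 h (prevention) or
72 h (reversal); the nadir finder returns the earliest minimum in a window,
for the early relaxation dip (generator default nadir at 2.5 h). The
synthetic response is `baseline·(1 + A(dose)·pulse(t) − depth·occ·dip(t))`
with AR(1) noise (SD 0.01, ρ 0.8); `pulse` rises with τ = 6 h and declines
exponentially (τ = 24 h) after a 24 h onset, and `A` is a Hill function of
dose (EC50 0.5 ng/ml, max 0.5 normalized units).

MRM chemistry is computed from first principles: monoisotopic residue
masses, water 18.0105646 Da, proton 1.007276 Da; y_n = C-terminal n
residues + water + z protons, b_n = N-terminal n residues + z protons. No
cysteine modification is applied by default (none of the three panel
peptides contains cysteine) but a fixed carbamidomethyl shift is available.
Computed values are reported at full precision internally and rounded to 2
decimals in tables; an annotation mechanism flags disagreements with
externally supplied (e.g. instrument-tuned) transition values rather than
adopting them. Tubulin normalization divides COL1A1 and ACTA peak areas by
the TBA1A area; wells with non-positive tubulin are flagged, not dropped
silently, and ratios left undefined.

## Dose–response and screening statistics

The concentration–response model is the three-parameter logistic in log10
concentration, `Y = Bottom + (Top − Bottom)/(1 + 10^(LogEC50 − X))`, fitted
by unweighted least squares (`scipy.optimize.curve_fit`) from deterministic
starts: Bottom/Top from dose-averaged extremes, LogEC50 from the
half-crossing of a linear interpolation. Bottom/Top are unconstrained by
default (anchoring to controls was considered and left as an option). A
flat response returns a censored fit, not an error; a fitted LogEC50
outside the tested range sets an above/below-range censor flag. Replicate
potencies are summarized as arithmetic mean ± sample SD on the linear
scale with `"> cmax"` annotations when all replicates are censored; for
rank statistics, censored potencies enter at their bound with a flag, and a
sensitivity option recomputes correlations without them.

Z′ = 1 − 3(σ_pos + σ_neg)/|μ_pos − μ_neg| with sample SDs (n−1); equal
control means yield a flagged undefined result. Spearman correlation is
rank (average ties) Pearson, with an exact permutation p-value for n ≤ 9
and the t approximation otherwise.

## Screening cascade

Primary hits: percent inhibition > 50% at 10 μM AND viability reduction
< 50%; toxic-but-effective compounds are kept with a rejected tier and
their viability value. Confirmation: uncensored IC50 < 10 μM from an
8-point, 3-fold dilution series starting at 30 μM. The end-to-end
validation screens a 200-compound synthetic library (10% actives, true
IC50 log-uniform in 30–1000 nM, efficacy 0.8–1.0) and scores hit calls
against the registry. Toxicity flags are assigned among inactives only, so
"true active" is an uncontaminated positive class for recall/FPR
accounting; a screen of toxic actives would require a different ground
truth convention.

The end-to-end screen (and the reversal protocol) runs at well-readout
level — per-well classified fractions are drawn binomially from the dose
rule rather than rendered and re-segmented — because the image chain is
already validated on control plates and rendering 200 dose series would
add hours of compute without exercising new code paths.

Reversal (de-differentiation) mode models state persistence: after 24 h of
stimulation and washout, wells remain at f_max unless a reversal-capable
compound pulls them toward f_min according to its occupancy; marker ratios
scale with the persisting fraction, and the readout moves to 96 h (72 h
post-washout for impedance).

## Problem sizes and determinism

Default validation plates use 32 control wells per role at 120 cells per
well (~7,500 training cells, ≥ 3,700 per class); the quantitative
behaviour is unchanged at half scale. All stochastic stages accept explicit
seeds; `scripts/acceptance.py --seed N` threads one seed through plate
simulation and training and recomputes every reported number from scratch.

## Known limitations

* The two printed precursor settings 441.73 (GVVGLPGQR) and 565.86
  (GYSFVTTAER) of the original instrument method differ from the
  monoisotopic values (441.76, 565.78), and the printed ACTA product 577.3
  does not correspond to a computed y8 of GYSFVTTAER (910.46); the
  calculator reports computed values and flags such mismatches rather than
  reverse-engineering instrument tuning.
* Percent-effect semantics when control classification drifts across
  plates (cross-plate transfer) are out of scope; the model is per-plate.
* The 3PL fitter is not validated for biphasic or bell-shaped responses;
  four/five-parameter variants are not implemented.
* Synthetic viability is a toxicity-dependent multiplicative reduction of
  cell count and signal, not a mechanistic viability assay model.
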