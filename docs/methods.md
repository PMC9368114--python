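# Methods

This note documents the models, conventions and design choices behind
`insectprint`, in the order the pipeline applies them.

## Measurement model and data layout

Each powdered-insect sample is measured under four conditions
("blocks"): extraction A (H₂O:MeOH 20:80) and extraction B (ethyl
acetate), each ionized in positive and negative mode, each in
triplicate, over an acquisition window of 75–1125 Da. Block identifiers
combine extraction and polarity: `meohpos`, `meohneg`, `etacpos`,
`etacneg`. A spectrum is a centroided peak list; the canonical
interchange format is a long-format CSV (sample_id, species,
extraction, polarity, replicate, mz, intensity), with mzML supported as
an ingestion path. I/O is lossless: peaks outside the acquisition
window are flagged, never dropped (range policy belongs to
preprocessing, not parsing). The mzML reader is a compact lxml-based
parser for the subset this workflow needs — centroided peak lists with
controlled-vocabulary terms for spectrum mode, scan polarity and binary
encoding (64/32-bit little-endian floats, optional zlib).

## Mass-spectrometric chemistry

Atomic monoisotopic masses are frozen in a constants table (C 12
exactly, H 1.00782503, N 14.0030740, O 15.99491462, S 31.97207117,
P 30.97376200) so every printed m/z is bit-reproducible. Singly charged
adducts use the proton-mass convention (1.007276 Da, electron mass
folded in): [M+H]⁺ = M + 1.007276, [M−H]⁻ = M − 1.007276, [M+NH₄]⁺ =
M + 18.033823, [M−H₂O+H]⁺ = M − 18.010565 + 1.007276. Reported m/z are
rounded half-up to 4 decimals and ppm errors ((obs − theo)/theo × 10⁶)
to 1 decimal, matching standard high-resolution reporting.

The bundled marker-ion table lists the species-discriminant ions of the
four insects with name, formula, adduct, species and block. At load,
each row's tabulated m/z is recomputed from its formula and adduct;
three rows are internally inconsistent (the glutamic-acid/oxoproline,
pentacosanediol and DG(24:0) entries) and are kept with a `flagged`
status — they participate in annotation and simulation at their
tabulated m/z but carry no exact-arithmetic guarantee. Block
assignments follow the observed chemistry: fatty-acid and lipid adducts
in the ethyl-acetate blocks, amino/organic acids in the
aqueous-methanol blocks.

## Synthetic cohort

The study's raw spectra are not publicly released, so the generator
produces a statistically explicit stand-in with the same design: 33
samples (12 *A. domesticus*, 11 *B. mori*, 5 *H. illucens*,
5 *T. molitor*) × 4 blocks × 3 replicates. Per block:

- **Background ions** (default 60) are drawn once, uniformly over the
  window with ≥ 0.1 Da separation from every other planted feature and
  its isotopologue, and shared across all samples with lognormal base
  abundances (median 10⁵ counts, σ = 1) — the non-informative common
  signal the missingness filter and the variable selection must reject.
- **Marker ions** from the bundled table are always present (median
  3 × 10⁵ counts off-species) and multiplied by `marker_fold`
  (default 10) in samples of their own species. An ion marking two
  species (palmitic acid) is elevated in both.
- **Isotopologues**: every peak with ≥ 1 carbon gets an M+1 partner at
  +1.00336 Da with relative intensity 0.011 per carbon (carbon-only
  model — enough to exercise isotope removal without full
  isotope-pattern machinery). Background ions are assigned plausible
  carbon counts (~1 C per 15–25 Da).
- **Noise**: multiplicative lognormal intensity noise with CV 0.25;
  multiplicative Gaussian mass jitter with σ = 2 ppm; Bernoulli dropout
  of non-marker peaks at 0.15 per replicate.

Defaults mirror the study design where stated (cohort composition,
triplicates, acquisition window, marker chemistry) and otherwise sit at
values typical of Orbitrap DART fingerprints (2 ppm jitter at 70k
resolution; 25% intensity CV; skewed lognormal abundances). One global
seed is split into independent substreams (layout, jitter, intensity,
dropout) so changing one noise knob never reshuffles the others;
generation is bit-reproducible.

The train/test split is stratified at the sample level by
largest-remainder apportionment with a floor of one test sample per
species: the default cohort splits 25/8 with test composition 3/3/1/1.
The per-species test composition is this package's choice; all three
replicates of a sample always share its role.

What the generator does **not** emulate: matrix effects, diet- and
rearing-driven within-species variation, electronic noise floors,
profile-mode peak shapes, and correlated (compound-class) background
structure. Passing tests on this cohort therefore demonstrate that the
workflow recovers a planted, well-separated species signal under
realistic mass/intensity noise — not that real insect powders are
separable; the study's 100% figures on real data cannot be reproduced
without the unreleased spectra.

## Preprocessing

Fixed stage order, each stage idempotent on its own output:

1. **Isotope removal**: peak P is removed iff some peak Q lies
   1.00336 Da below it within 10 ppm (at P) with strictly higher
   intensity; the test runs against the original list, so an M+2 falls
   through its (removed) M+1. 10 ppm is comfortable at 70k FWHM.
2. **Alignment**: all peaks of a block are pooled, sorted, and split
   where the gap between consecutive m/z exceeds 5 ppm (single-linkage
   with chain breaking). One peak per spectrum per bin (most intense
   wins); bin m/z is the intensity-weighted mean.
3. **Missingness filter**: a bin is dropped iff missing in strictly
   more than 75% of replicate rows, assessed per block over all rows
   jointly (blocks are preprocessed before fusion).
4. **Imputation**: missing cells get 1/5 of the bin's lowest positive
   observed intensity. The minimum is per bin, not global, following
   the common metabolomics-suite behaviour.
5. **Sum normalization**: each row becomes a composition (sums to 1).
6. **Pareto scaling**: (x − mean)/√sd per bin, with the sample
   standard deviation (n − 1 divisor, the R/metabolomics convention);
   constant bins map to 0. Parameters are learned on training rows
   only and applied unchanged to held-out rows — leakage-safe, at the
   cost of test rows not being exactly centered.

## Fusion and variable selection

Low-level fusion concatenates all bins of all blocks in fixed order
(meohpos, meohneg, etacpos, etacneg) for PCA exploration (mean-centered
SVD; component signs fixed so the largest-|loading| element is
positive).

Mid-level fusion is the workflow's core. Per block, PLS-DA is fit on
the training rows against a column-centered one-hot class matrix
(Y never variance-scaled; X Pareto-scaled upstream). Each component's
weight vector is computed exactly as the dominant left singular vector
of the deflated cross-covariance X′Y — the fixed point of the NIPALS
iteration — rather than by power iteration: with c classes the
centered Y has rank c − 1, and on late components the iteration can
stall on a near-degenerate spectrum, whereas the direct solution is
deterministic and was verified against an independently converged
reference PLS implementation to < 10⁻⁶. X and Y are deflated by the X
scores after every component; five components are used, matching the
reference workflow.

Importance is quantified by VIP over the five components,
VIP_j = √(p · Σ_a SSY_a (w_ja/‖w_a‖)² / Σ_a SSY_a) with
SSY_a = ‖t_a‖²‖q_a‖², so mean(VIP²) = 1 identically. Selection takes
each block's top ⌈18/4⌉ + 1 = 6 candidates, then keeps the global top
18 with a floor of two per block (floor scales down to max(1, total/4)
for small totals); ties break by higher VIP, lower m/z, block order.
The per-block floor reflects that all four blocks contribute
discriminant ions; the 18-variable total is the reference workflow's
choice.

The selected ions are clustered with Pearson distance (1 − r) and Ward
linkage (scipy's Ward update applied to the condensed correlation
distances, the common heatmap practice); a constant ion sits at the
maximum distance 1 from everything. The exported heatmap matrix holds
per-species means of the scaled intensities (rows = ions, columns =
species); species-mean rather than replicate-level columns is this
package's choice.

## Classification and validation

A 500-tree random forest with √p candidate features per split and a
fixed seed operates on replicate-level rows of the 18 fused ions.
Validation is 10-times repeated, species-stratified, sample-grouped
5-fold cross-validation: replicates of a sample never straddle a fold
(grouping prevents replicate leakage), and stratification falls back to
plain grouped folds with a logged warning when a class is too small
(e.g. leave-one-sample-out). A sample's call is the majority vote over
its replicate predictions, ties broken by highest mean vote fraction;
the report carries per-repeat sample-level accuracies and a final
confusion matrix of modal calls across repeats. Held-out evaluation
guards against train/test sample overlap. Sensitivity and specificity
are one-vs-rest per species with macro averages as headline figures
(any averaging convention coincides at 100%).

## Negative controls

Two controls verify the pipeline finds signal only when signal exists:

- **No-signal cohort** (`marker_fold = 1`): species are exchangeable.
  Cross-validating the classifier alone on ions pre-selected from the
  full training set overstates no-signal accuracy (~0.40–0.46 here) —
  the classic bias of supervised feature selection performed outside
  the folds. The honest control, `pipeline_cv`, re-runs the per-block
  PLS-DA/VIP selection inside every training fold and lands within the
  95% binomial band around chance. The main workflow deliberately keeps
  selection outside the CV loop to mirror the reference protocol (its
  validity there rests on the held-out test set, not the CV figure).
- **Marker recovery**: on the no-signal cohort, planted-marker
  membership among the 18 selected ions collapses to the hypergeometric
  chance level (≈ 1 of 16), with true or permuted labels alike. A
  caveat worth stating: with the signal present (10-fold markers),
  permuting labels does *not* collapse recovery — Pareto scaling
  preserves the markers' dominant between-sample variance, and PLS
  weight vectors track high-variance directions whatever Y is. VIP
  selection on Pareto-scaled data is partly an (unsupervised) variance
  filter; label permutation tests of *selection* are only meaningful
  against variance-matched nulls.

## Numerical conventions and limitations

- Rounding half-up (4 decimals m/z, 1 decimal ppm); frozen atomic
  masses; all RNG via seeded numpy Generators with per-purpose
  substreams; end-to-end runs are bit-reproducible per config.
- Alignment assumes features are separated by ≫ 5 ppm; chimeric bins
  from overlapping features are not resolved (DART of complex powders
  can contain them).
- Default problem sizes (33 samples, ~60 background ions/block) keep a
  full pipeline run at well under a minute on one core; the repeated
  CV dominates the cost (50 forest fits).
- The classifier offers no "none of the four species" rejection;
  partial adulteration and novel species are out of scope.
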