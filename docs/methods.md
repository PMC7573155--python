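# Methods

`fcresponse` implements a treatment-response-prediction analysis for
within-subject pharmacological-challenge fMRI studies: each subject
contributes one functional-connectivity matrix under an active (verum)
challenge and one under placebo, and the question is whether the
verum−placebo connectivity difference predicts how a subject's depressive
symptoms change over a subsequent treatment course. The package covers the
four stages of that analysis — questionnaire factor extraction,
connectivity-matrix construction, network-based pre-selection, and
cross-validated prediction — together with a synthetic-data generator that
plants known ground truth through all of them.

## Questionnaire factor model

Item scores (HAM-D-like 17-item or BDI-like 21-item layouts, integer
scales) are modeled as `x = Λ f + ε` with orthogonal standard-normal latent
factors. The fitting pipeline mirrors the classical exploratory route:

1. **Sampling adequacy.** KMO and per-item MSA are computed from the
   anti-image correlations `a_ij = −R⁻¹_ij / √(R⁻¹_ii R⁻¹_jj)`. While
   KMO ≤ 0.5 the item with the lowest MSA is removed (ties broken by
   original item order, so the loop is deterministic) and the analysis
   repeated.
2. **Factor count** by the Kaiser criterion: eigenvalues of R strictly
   greater than 1.
3. **Principal-axis extraction**, iterating communalities on the reduced
   correlation matrix from squared-multiple-correlation starting values.
   The communality fixed-point converges only geometrically; convergence is
   declared when the largest communality change falls below 1e−3 within
   100 iterations, the convention of the classical statistical packages.
   A far stricter tolerance would flag perfectly well-behaved data as
   non-convergent — under the item-removal rule below that would silently
   delete good items. Non-convergence and Heywood cases are flagged, and
   the fitting loop responds by removing the item with the next-lowest MSA,
   reproducing how such failures are handled in practice.
4. **Varimax rotation** with Kaiser row normalization, implemented by
   pairwise planar rotations with the closed-form quartic angle. The
   gradient/SVD fixed-point alternative can stall on symmetric loading
   configurations (it sits at a stationary point of the criterion); the
   pairwise sweep cannot, and the returned `T` satisfies `Λ_rot = Λ T`
   with `TᵀT = I` to 1e−10 and unchanged communalities.
5. **Anderson–Rubin weights** `W = Ψ⁻¹Λ (ΛᵀΨ⁻¹RΨ⁻¹Λ)^(−1/2)`, which make
   the factor scores exactly orthonormal (sample covariance = identity to
   machine precision) on the fitting sample.

Post-treatment tables are **projected**: standardized with the pre-sample
means and SDs (sample SD, n−1) stored in the model and multiplied by the
stored weights. Nothing about the post data enters the factor definition,
so treatment response cannot leak into it. Sum scores always use all
original items, including any dropped from the factor solution — item
removal optimizes factors, not the clinical total. Missing post-visit
totals are linearly interpolated from the adjacent visits and rounded up
(`ceil` of the midpoint). Remission is a post total ≤ 7; response is a
total-score reduction of at least 50%.

Correlations are Pearson on the raw integer scores; polychoric models are
deliberately out of scope.

## Connectivity construction

ROI time series come from 10 mm-diameter spheres around user-supplied
mm-space centers on a 2 mm isotropic grid. A voxel belongs to a sphere iff
its center is within 5 mm (inclusive — no lattice point of a 2 mm grid
falls at exactly 5 mm, so the boundary convention is provably irrelevant)
of the ROI center; contested voxels go to the nearer center, ties to the
lower node id; sets are intersected with the conjunction of all subject
masks. A grid-aligned unmasked sphere contains 81 voxels.

Nuisance regression and band-pass filtering (0.01–0.10 Hz; study TR
2.44 s) happen **in one model**: the filter is a projection onto a
discrete cosine/sine basis at the DFT grid frequencies of the full run,
evaluated at the retained (non-censored) frame times; nuisance regressors
(top-5 tissue PCs by default) are first band-limited by projection onto
the passband basis and then regressed out jointly with the stopband basis.
Residuals are therefore orthogonal to the filtered nuisance set and carry
no out-of-band variance, and censored frames never re-enter. On uncensored
runs this equals FFT bin-zeroing to numerical precision (the provided fast
path); the cleaning operator is idempotent. Censored frames are dropped,
not interpolated, and the retained count is recorded.

Cleaned series are Pearson-correlated and Fisher-z transformed
(`z = atanh r`, zero diagonal). Zero-variance nodes and |r| = 1 pairs are
rejected as degenerate input. The per-subject mean connectivity — the mean
upper-triangle z pooled over both conditions — is the global covariate of
the downstream models. Difference matrices (verum − placebo) are computed
per analysis run, never cached across masks.

## Network-based statistics

Per edge, OLS of the connectivity difference on [intercept, score change,
sex, age, mean connectivity]; the edge-forming threshold is the one-sided
t quantile at p ≤ 0.001 for the available df. Suprathreshold edges form a
graph whose maximal node-connected components are scored by **extent**
(edge count) and **intensity** (summed t excess over the threshold). Both
statistics are computed on every run. FWER control uses a max-statistic
permutation null with **Freedman–Lane** residual permutation: fit the
covariates-only model, permute its residual rows, re-add the reduced fit,
re-estimate, and record the maximum component statistic (10,000
permutations by default; α = 0.10 to admit trend-level networks; p-values
use the +1-smoothed estimator, minimum attainable 1/(n_perm+1)). With no
covariates the scheme reduces exactly to simple row permutation, which is
tested. Each contrast direction is run separately; results are labeled
with the permutation scheme. Pre-selection tests are not corrected for
multiplicity, by design — they only nominate factors for prediction.

A numerical caveat the simulations quantify: at a sparse edge threshold
the extent statistic's null concentrates on very few integer values, so
extent-based rejection is valid but conservative (its rejection rate under
the null sits well below α); intensity, being continuous, is calibrated
almost exactly. Inference should therefore not be read off extent alone at
small component sizes.

## Prediction

On a training set, each edge receives the absolute partial Pearson
correlation between its connectivity difference and the score change
(controlling sex, age, mean connectivity; plain correlation in the reduced
no-covariate models), scaled by the sample SD of all absolute correlations
within the selection. The **FC predictor** of a subject is the weighted
average of their difference matrix over the selected edges — a weighted
mean, so uniform weight rescaling (including the SD scaling) provably
cannot change predictions; the scaling is kept because weight magnitudes
are reported and must be comparable across folds. Signed weights are
available for comparison and coincide with unsigned ones whenever all
selected sample correlations share one sign.

Edge selection comes in three strategies: the full-sample NBS components
(**circular** — retained deliberately, and always labeled, to demonstrate
double dipping), the NBS t threshold recomputed on each training fold
(with the fold's own df), and no threshold.

Score change is regressed on [intercept, FC predictor, covariates] by IRLS
with the Tukey bisquare ψ (tuning 4.685, 95% Gaussian efficiency), scale
re-estimated each iteration as MAD/0.6745 of the residuals, initialized at
least squares; an exact fit returns the least-squares solution, and
non-convergence returns the last iterate flagged. Validation uses LOOCV
(summary: Pearson r of the pooled held-out predictions) and repeated
3-fold CV without role reversal — per redraw the subjects are split into
three folds and one randomly chosen fold is the test set, so the model
never trains on the smaller share; the summary is the median per-redraw r
(1,000 redraws by default). Per-redraw two-sided Pearson p-values are
summarized by their median and Sidak-adjusted with m = 7 (six factors plus
the sum score). Degenerate folds (empty selection, zero-variance
predictor) are recorded and excluded rather than aborting the run.

Median weight matrices treat unselected edges as weight 0, which is why
thresholded 3-fold runs show mostly zero medians. Post-hoc classification
applies the clinical cutoffs to the threshold-free predictions (averaged
per subject across 3CV redraws): predicted post = pre − predicted
reduction, predicted remission iff ≤ 7, predicted response iff the
predicted reduction reaches half the pre total; AUC is the Mann–Whitney
rank statistic (ties ½) and BAC the mean of sensitivity and specificity.
How the original analysis set the BAC decision threshold is not
documented; the clinical-cutoff-on-predictions rule used here is one
reading and is labeled as such in outputs.

## Synthetic-data generator

The generator defines the study conditions for every simulation:

* **Questionnaire**: n subjects × 17 items, six orthogonal factors,
  simple-structure loadings (0.75–0.85 primaries in the shipped
  configurations), item noise SD 0.6, scores discretized by rounding and
  clipping to the 0–4 item range (continuous values returned for
  calibration). Post items come from shifted latent factors (default mean
  shift −0.8, innovation SD 1.0), so true factor changes exist per subject.
* **Connectivity**: placebo matrices are symmetric N(0, 0.3²) z-noise with
  zero diagonal. The verum matrix adds a condition-difference term with
  the same 0.3 SD on *every* edge, and on the planted edges that term is
  `σ(ρ·ŝ + √(1−ρ²)ε)`, making the population correlation between the edge
  difference and the score change exactly ρ. Giving all edges difference
  noise is a deliberate design choice: if non-planted edges had an exactly
  zero difference, every null edge-wise GLM would be degenerate and the
  permutation null undefined. The planted effect still enters the verum
  condition only.
* **Planted topology**: a hub-and-spokes star. Any subset of detected star
  edges remains connected, so detection power measures the statistics, not
  the fragmentation of a chain; the emulated phenomenon is one coherent
  subnetwork around a hub region.
* **Covariates**: balanced binary sex, age uniform on 20–55, optionally
  correlated with the score change at configurable levels (default
  independent).
* **Imaging fixture**: a small 4-D NIfTI volume with planted ROI signals
  in the spheres, mixtures of nuisance signals in two tissue masks (and
  optionally leaked into ROI voxels), and white noise.

What the generator does **not** emulate: realistic hemodynamics, motion,
scanner artifacts, spatial autocorrelation of connectivity noise, item
distributions of any real clinical sample, or between-site heterogeneity.
Passing tests therefore certify the statistical machinery — calibration,
power at a stated effect size, circularity detection, recovery of planted
structure — not performance on any particular clinical dataset.

## Simulation designs

The study-scale experiments (in `fcresponse.experiments`, shared by the
test suite and `scripts/acceptance.py`) use these problem sizes, chosen as
the package's standard configurations:

* FWER calibration: 200 null studies, n = 30 subjects, 60 nodes
  (1,770 edges), 500 permutations, α = 0.05.
* NBS power: 100 replicates, planted 10-edge star, effect ρ = 0.6,
  n = 40, 60 nodes, 500 permutations, detection = ≥ 50% of planted edges
  inside α = 0.10-significant components.
* Circularity: 50 null studies, 60 nodes; the "spurious selection" is the
  full-sample suprathreshold components at an edge-forming p ≤ 0.01 (at
  60 nodes that threshold leaves a non-empty selection with probability
  ≈ 1, so the demonstration is defined on every replicate), compared with
  honest strategy-C LOOCV on the same studies.
* Honest-CV null calibration: 50 null studies, n = 30, 46 nodes
  (1,035 edges — the closest triangular number to 1,000), LOOCV pooled r
  and 3-fold medians over 200 redraws.
* Factor recovery: n = 500, 17 items, 6 factors.

## Known limitations

* **Pooled LOOCV r is negatively biased under the null** (median ≈ −0.12
  at n = 30 with covariates in the calibration design): every fold's
  intercept/covariate fit tracks the training mean, which is
  anti-correlated with the held-out value. This is a property of the
  procedure itself — a plain OLS LOOCV on pure noise shows the same
  shift — and is reported, not corrected, by the calibration experiment.
  The 3-fold median does not share it.
* The unsigned-weight FC predictor has high between-study variance when
  the effect is sparse: the contribution of the ~1,000 null edges is a
  zero-mean random walk comparable in scale to the planted signal, so
  single-study honest correlations scatter widely around the replicate
  median.
* Extent-based NBS inference is conservative at sparse thresholds (see
  above).
* The item-removal loop, like its real-world counterpart, can in
  principle remove informative items under severe sampling noise; the
  audit trail of drops (item, MSA at removal) is stored in the model for
  exactly that reason.
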