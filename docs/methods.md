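# Methods

`dynsig` extracts interpretable dynamical signatures from multi-subject
multivariate time series — per-region ("univariate") features, pairwise
coupling statistics, and their combinations — and evaluates them as
case–control classifiers under a leakage-free repeated cross-validation and
permutation-null protocol. This note records the models, estimator choices,
defaults, and known limitations.

## Data model

A cohort is N subjects, each an R × T real matrix (regions × timepoints) on
a uniform grid with spacing `tr_seconds` (the repetition time, seconds).
Subject order follows the participants table everywhere, so every tensor and
fold plan indexes subjects identically. Quality control excludes subjects
whose mean framewise displacement exceeds 0.55 mm (strict inequality; FD is
the Power convention: summed absolute frame-to-frame translations plus
rotations converted to arc length on a 50 mm sphere) and subjects whose
every regional series is constant. A region constant in only *some* subject
is an error at feature time by default — silently dropping it would change R
and every downstream dimension — with an explicit opt-in flag to drop the
region cohort-wide instead.

## Synthetic cohorts

The generator is a first-order vector autoregression
x_t = A x_{t−1} + ε_t, ε_t ~ N(0, diag(σ²)), simulated per subject with
independent noise streams spawned from a master seed (`SeedSequence.spawn`,
so removing one subject never perturbs another's realization) and a 100-step
burn-in. A holds the regional autocorrelation (diagonal, default 0.3 —
mid-range for slow hemodynamic-like signals at TR ≈ 2 s) and inter-regional
coupling (off-diagonal; templates "none", "chain", "dense(ρ)"). Group
effects modify the case group only: a multiplicative regional noise-SD
change, an additive diagonal AR shift (timescale change), and an additive
coupling shift — the three effect classes the downstream features are built
to detect. Stationarity (spectral radius of A < 1) is checked before
simulation. An optional motion-like confound adds a shared AR(1) global
component scaled by a synthetic per-subject mean-FD drawn with an optional
group offset.

Defaults for the calibration experiments are N = 20+20, R = 6, T = 120,
TR = 2 s: small enough for desk-scale runs, large enough for stratified
10-fold cross-validation and stable spectral estimates. What the generator
does **not** emulate: hemodynamic filtering and its characteristic spectrum,
site/scanner effects, heavy-tailed motion artifacts, and spatially
structured parcellation geometry. Passing tests therefore certify the
statistical machinery (estimators, cross-validation, calibration), not
performance claims about any particular imaging cohort.

## Univariate features (25 per region)

Mean and SD (sample SD, T−1 denominator) are computed on the raw series —
they carry the measurement scale on purpose. fALFF is the share of non-DC
periodogram power in 0.01–0.08 Hz: plain one-sided periodogram of the
mean-removed series, no taper, band edges inclusive, DC excluded from the
denominator (the ratio is estimator-robust; this is the simplest
reproducible choice). The remaining 22 features are a native implementation
of the canonical catch22 set, computed on the z-scored series so that all
22 are invariant to positive affine transforms. Numerical conventions fixed
here (checked by definitional-oracle and property tests):

- ACFs use the biased (1/N) autocovariance normalization via FFT.
- `ACF_timescale` interpolates the 1/e crossing linearly between lags.
- Histogram modes use equal-width bins spanning [min, max]; tied fullest
  bins average their centers.
- Symbolic features use tercile coding with linear-interpolation quantiles.
- Spectral summaries use a one-sided periodogram on an angular-frequency
  grid; `centroid_freq` is the cumulative-power half-point,
  `low_freq_power` the integral over the lowest fifth of frequencies.
- Fluctuation analysis (`DFA`, `rs_range`) coarse-grains at lag 2,
  cumulates, evaluates 50 log-spaced window sizes in [5, n/2], and returns
  the proportion of window sizes in the first regime of the best two-line
  fit to the log-log fluctuation plot; the minimum points per regime adapts
  from 6 to 3 when fewer than 12 distinct window sizes exist (T below
  ~120), and the feature is undefined (NaN, logged) below 8 sizes.
- `periodicity` detrends with a least-squares cubic spline (two interior
  knots at T/3 and 2T/3) and reports the first ACF peak exceeding the
  preceding trough by at least 0.01 with positive height, else 0.

Undefined features are stored as NaN with a log entry and median-imputed
later, inside each training fold only.

## Pairwise statistics (14 per region pair)

All SPIs are computed on z-scored series. Directed statistics (ANM, DI,
transfer entropy, spectral Granger causality, both phase-slope indices) are
evaluated over all R(R−1) ordered pairs; undirected ones over the R(R−1)/2
unordered pairs. One spectral convention serves every frequency-domain
statistic: Welch with a Hann window, 50% overlap, and segment length
min(128, ⌊2T/3⌋) so at least two segments are always averaged (one segment
makes the cross-spectral matrix rank one: coherence degenerates to 1 and
spectral factorization is impossible).

- **Pearson**: empirical covariance of the z-scored pair.
- **DTW**: unconstrained dynamic-programming alignment with squared local
  cost; the square root of the optimal accumulated cost is returned
  (verified against exhaustive alignment enumeration at short lengths).
  **barycenter_DTW** is the time-average of the DTW barycenter (DBA: mean
  initialization, at most 10 refinement sweeps).
- **coherence_magnitude**: mean over positive frequencies of
  |S_xy|/√(S_xx S_yy). **PLI**: |mean sign sin(Δφ)| with instantaneous
  phases from the analytic signal. **power_envelope_corr**: Pearson
  correlation of analytic-signal amplitude envelopes.
- **PSI**: Σ_f Im(C*(f) C(f+δf)) over the full band, δf one bin, with the
  coherency C oriented so a positive value means x leads y (scipy's
  cross-spectrum is conjugated to achieve this). The time-frequency variant
  averages PSI over ⌈T/4⌉-length windows at 50% overlap.
- **Gaussian information measures** with history length 1:
  TE(x→y) = ½ ln(Var(y_t|y_{t−1}) / Var(y_t|y_{t−1},x_{t−1})); DI uses the
  contemporaneous source x_t instead of x_{t−1}. **Φ\*** is the Gaussian
  mismatched-decoding integrated-information proxy for the bipartition
  {x},{y} at lag 1: Φ* = I(present; past) − max_β Ĩ(β), where the decoder
  predicts each part's present from its own past only and the scalar β is
  optimized numerically on [0, 1]. All three are ≈ 0 for independent pairs.
- **Spectral Granger causality**: nonparametric, via Wilson's matricial
  spectral factorization of the Welch cross-spectral matrix (zero-padded to
  a 512-point frequency grid — at coarser grids the implied autocovariance
  aliases and the causal projection drifts), initialized from the Cholesky
  factor of the zero-lag autocovariance, at most 300 sweeps, accepted when
  the relative factorization residual is below 10⁻²; the Geweke
  frequency-wise measure is averaged over non-DC frequencies.
- **Cointegration**: Engle–Granger ADF statistic (constant, one lagged
  difference) on the residuals of each regression direction, symmetrized by
  averaging the two directions.
- **ANM**: kernel-ridge regression of y on x (RBF kernel,
  median-heuristic bandwidth, ridge 0.1), scored by the biased HSIC
  V-statistic between residuals and cause; series longer than 500 samples
  are thinned evenly (the kernels are O(n²)). Lower = more consistent with
  x→y.

Bit-exact parity with any particular published pairwise-statistics library
is not claimed for DTW normalization, the barycenter summary, the DI
history convention, the Φ* optimizer, or the cointegration variant; the
contracts are the mathematical properties above plus these stated choices.

## Representations and classification

Five designs per cohort: `A_region(r)` (25 features of one region),
`A_feature(f)` (one feature across R regions), `A_uni_combo` (R·F columns,
region-major), `A_FC(spi)` (P pair columns), and `A_FC_combo(spi)`
(P + R·F columns — concatenation, not a product space). Column provenance
maps every design column back to exactly one tensor cell.

Evaluation is stratified 10-fold cross-validation repeated 10 times
(100 fold metrics), all models sharing the fold plan derived from one seed.
Per fold: training-column medians impute missing values; each column is
normalized by the scaled outlier-robust sigmoid
g(v) = 1/(1 + exp(−(v − median)/(IQR/1.349))) (mean/SD fallback when the
IQR is zero; fully constant columns map to 0.5 and are flagged), linearly
rescaled so the training values span [0, 1]; test values reuse the training
parameters unchanged and may leave [0, 1] (no clipping). The classifier is
a linear (hinge-loss) SVM, C = 1, with inverse-probability sample weights
n/(2 n_class); balanced accuracy (mean of sensitivity and specificity, in
percent) is the primary metric, AUC from the signed decision values is
recorded alongside. Confound-only classifiers reuse the identical pipeline
on covariate columns.

## Significance and model comparison

The permutation null shuffles labels once per permutation (before fold
construction; stratification uses the shuffled labels, preserving class
counts), runs the full repeated-CV harness, and records the mean fold
metric; 1000 permutations is the reference setting, and a documented
`light` mode runs one repeat inside each permutation for desk-scale use.
A Gaussian fitted to the null's two moments supplies one-tailed p-values
below the 1/n_perm resolution; Benjamini–Hochberg (step-up, ties preserved)
controls the FDR within each model family. The fitted null mean carries a
sampling error of σ/√n_perm, which shifts all p-values of a family
coherently — use enough permutations that this is small relative to σ
(≥ 200; 400 in the calibration suite here).

Models evaluated on shared folds are compared with the corrected resampled
t-test: T = d̄ / √((1/(kr) + n_test/n_train) s_d²) with kr − 1 degrees of
freedom. Calibration, measured here by simulation: for pairs of
equally-performing models with genuine (equal) signal on a shared fold
plan, the empirical type-I rate at α = 0.05 is ≈ 0.05–0.06. For pairs of
*chance-level* models built from independent noise, the heuristic variance
inflation underestimates the between-dataset component by roughly 30% and
the test is liberal (empirical size ≈ 0.10); with the dataset shared and
only fold plans varying it is strongly conservative. This is a property of
the published correction, not of this implementation; interpret comparisons
of near-chance models cautiously.

Per-fold model selection picks, within each training fold, the candidate
with the best in-sample training balanced accuracy (refit on training rows,
scored on training rows; exact ties retain the mean of the tied candidates'
test accuracies). The wide coupling families are screened in the space of
the first 10 principal components fit on the training rows (a whole-data
PCA variant is available behind a flag for replication of protocols that
fit PCA once), and the winner's full-dimensional representation is then
scored out of sample. PCA reduction utilities likewise fit components on
training rows only.

## Problem sizes used in the shipped experiments

The calibration and recovery experiments run at N = 40–60, R = 6, T = 120,
with 200–400 permutations and 100–500 replicates — sizes chosen so the
whole suite runs comfortably on a single CPU while leaving the statistical
assertions well-powered. The dimensional contracts are exercised at the
full R = 82 / R = 48 scales symbolically (pair enumeration and design-width
arithmetic), which is exact and free.

## Known limitations

- The 22-feature set follows the published algorithm definitions but fixes
  its own numerical conventions where the originals leave room (binning,
  quantiles, spectral grid); values are not guaranteed bit-identical to any
  specific reference binary.
- Gaussian estimators (TE, DI, Φ*) measure linear-Gaussian dependence only.
- The spectral Granger estimator is biased upward at short T (smoothed
  spectra); comparisons across conditions at fixed T remain meaningful.
- The corrected resampled t-test is a heuristic; see the calibration
  discussion above.
- The permutation null conditions on the observed feature matrix; its
  fitted mean inherits permutation sampling noise that propagates to every
  p-value of the family.
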