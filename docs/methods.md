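# Methods

`tausynth` implements covariate-conditioned synthesis of 3D tau-PET SUVR
volumes from T1-weighted MRI, together with everything needed to train and
evaluate the method at desk scale: a synthetic brain-phantom generator, the
auxiliary tabular estimators, the synthesis network and its training
protocol, image-fidelity metrics, and the downstream statistical battery.
This note records the model, its assumptions, the defaults, and the design
choices that were genuinely open.

## The three-stage synthesis model

**Stage 1 — tabular auxiliaries.** From demographics, vitals, APOE4 count
and (when available) plasma biomarkers, gradient-boosted regressors estimate
each ROI's mean tau SUVR `tau_hat_r` together with an uncertainty
`sigma_hat_r`, plus the temporal meta-ROI composite (MetaTempTau); a boosted
classifier estimates amyloid positivity and a k-nearest-neighbour regressor
estimates MMSE. Missing covariates are imputed first by a KNN scheme with
k = round(sqrt(p)) neighbours (p = number of features), uniform neighbour
weights, and Euclidean distances over standardized, mutually observed
columns; categorical columns are one-hot encoded for distance computation.
When a fitted pipeline is applied to new subjects, the training rows act as
imputation donors, so validation tables may lack entire covariate panels
(e.g. no plasma assays).

The Gaussian output head is realised as two boosted models per ROI: an
L2 fit of the mean and a second fit of the squared residual, with
`sigma_hat = sqrt(max(E[res^2], floor^2))`. Residuals are taken out-of-fold
(internal 5-fold) whenever at least 40 training rows are available, which
keeps the SD estimate from collapsing toward zero on interpolated points.
The meta-ROI estimator is trained directly by default; a `derived` mode
reconstructs it from the regional predictions with voxel-count weights for
exact consistency.

**Stage 2 — conditionally decoded attention U-Net.** The MRI passes through
a standard two-convolution-per-level encoder (PReLU activations, dropout,
non-affine instance normalization, 2x average pooling). Decoding upsamples
by nearest-neighbour and applies a *conditionally parameterized* convolution:
a bank of expert kernels (default 4) is mixed per subject with softmax
routing weights computed from the conditioning vector — age, sex (coded
±1), education, predicted MMSE and predicted MetaTempTau, each z-scored
with training-set statistics. Skip connections are gated by additive
attention (two 1x1x1 projections, ReLU, 1x1x1 + sigmoid), yielding
coefficients in [0, 1]. The decoder output is projected to a single-channel
initial prediction Z on the full grid.

**Stage 3 — regional-tau prompt modulation.** A learned base prompt F (4
channels at output resolution) is adjusted per subject:

    F_mod = F + ConvBlocks(F_c ⊕ S_hat ⊕ Gamma_hat)
    P_hat = ReLU(Conv(Z ⊕ ConvBlocks(F_mod ⊕ Z)))

where ⊕ concatenates channels, `Gamma_hat` holds `tau_hat_r` at every voxel
of ROI r (zero on background), `S_hat` holds the SDs analogously, and `F_c`
is selected from a two-slot bank by predicted amyloid status. `ConvBlocks`
is three (conv → PReLU → dropout → instance-norm) stages. The final `Conv`
is one such stage followed by a plain 1x1x1 projection before the ReLU.
The last convolution of the modulation block starts at zero, so the
modulation path is exactly the identity (`F_mod == F`) at initialization —
a residual start that stabilizes early training. The ReLU derivative is
taken as 1 at exactly 0 so this parked path keeps a live gradient.
Whether `Gamma_hat` enters the modulation block or only the output head is
ambiguous in the method's formulas; the default follows the displayed
modulation formula, and `modulation_includes_gamma=False` switches to the
alternative reading (gamma concatenated at the head instead).

An ablated configuration removes conditioning and modulation entirely,
reducing the model to a plain attention U-Net whose output is a function of
the MRI alone; it is used as the covariate-free baseline.

**Numerical substrate.** No deep-learning framework is assumed: the network
runs on an in-package reverse-mode autodiff engine (numpy, float64) with
im2col-based stride-1 'same' 3D convolutions, validated op-by-op against
central finite differences. The same code path runs at 12³/16³ (tests,
desk-scale experiments) and larger grids; the architecture only requires
grid dimensions divisible by 2^(levels−1).

## Training protocol

The objective is an ROI-weighted voxel MSE: residuals in ROI r are scaled by
a configurable weight w_r (default 2 for temporal meta-ROI members, 1
elsewhere — the composite the evaluation emphasizes), background weight 1;
the weighted squares are averaged over voxels, then over subjects. AdamW
with learning rate 1e-3 and decoupled weight decay 1e-3, batch size 2
(batch 4 in the desk-scale runs for throughput), a reduce-on-plateau
schedule on validation loss (factor 0.5, patience 2), and early stopping
after 5 epochs without relative improvement > 1e-4. The best-validation
checkpoint is returned. The validation subset defaults to 10% of the
training split; which loss the plateau schedule monitors is not pinned down
by the protocol description, so validation loss is used.

Cross-validation uses five folds balanced on amyloid status and MetaTempTau:
subjects are stratified on (status × tau-quantile bin), with the bin count
shrunk for small cohorts so that strata stay fillable; longitudinal visits
of one subject share a fold. All stage-1 models are refit inside each fold
on that fold's training partition only, and a guard raises if any held-out
row id reaches a predictor that was fitted on it.

## The phantom generator

Phantoms emulate the statistical structure the analyses assume, not anatomy:

- **Atlas**: a Voronoi parcellation of an ellipsoidal brain mask (default
  8 ROIs in tests; the ROI count is free — 32 hemisphere-paired regions
  mirrors the full analysis). ROI seeds are drawn in the left hemisphere and
  mirrored. Braak onset stages follow distance from a medial-inferior
  anchor: nearest third of pairs onsets at stages 1–2 (medial temporal),
  middle third at 3–4 (temporal), rest at 5–6 (neocortical). The temporal
  meta-ROI collects all stage-1–4 regions; its composite is the
  voxel-count-weighted mean, equivalent to the mean over the merged mask
  (the aggregation is stated only as a "weighted average"; voxel-count
  weights are the choice consistent with SUVR over a union mask).
- **Disease process**: an ordinal Braak group (0, I/II, III/IV, V/VI) drawn
  from `stage_probs` (default 0.40/0.25/0.20/0.15), shifted toward higher
  groups by APOE4 count (+0.6 log-odds per allele per step). ROI mean tau
  is baseline 1.0 SUVR plus an onset-tier increment (0.9/0.7/0.5 for tiers
  1–2/3–4/5–6) scaled by a subject severity factor (1.0 ± 0.25, clipped),
  applied when the ROI's onset stage ≤ 2×group. Voxel noise is Gaussian
  (sd 0.08 SUVR), floored at 0.05 SUVR so MAPE stays defined.
- **MRI**: a smooth ellipsoidal tissue template minus `atrophy_gain` (0.25)
  times the local tau excess, plus noise (sd 0.05) — tau-coupled atrophy is
  the only disease signal in the MRI channel.
- **Covariates**: plasma p-tau217 is linear in true MetaTempTau (slope 0.35,
  noise sd 0.06 — implying r ≈ 0.9 with the default tau spread); MMSE is a
  ceiling of 29.5 minus 9 points per unit neocortical tau excess and 2 per
  unit meta-temporal excess, plus noise (sd 1), clipped to [0, 30];
  NfL/GFAP drift upward with stage; Aβ40/42 reflect amyloid status.
  Demographics and vitals use cohort-typical means and spreads (age 73 ± 7,
  education 16.4 ± 2.6, etc.). Diagnosis is thresholded on the noise-free
  MMSE at 27 (CN/MCI) and 24 (MCI/Dem) — a simple monotone rule, not a
  clinical claim. Default missingness: 30% per plasma marker, 5% vitals and
  APOE, 2% other fields, never age/sex.
- **Longitudinal**: per-subject annual slope (default 0.05 ± 0.02 SUVR/yr)
  added to affected-ROI means at each visit; visits share identity and
  covariates, with cognition re-evaluated per visit.

What the phantoms do **not** emulate: anatomical contrast and geometry,
off-target tracer binding, registration/partial-volume artefacts, non-linear
covariate relationships, and site/tracer heterogeneity. Passing tests
therefore demonstrate that the pipeline's machinery is correct and that
covariate conditioning helps when covariates genuinely carry tau signal —
not that real-cohort fidelity numbers transfer.

## Metrics

Regional Pearson correlations are computed across subjects per ROI and
averaged into Corr_AVG (zero-variance ROIs are excluded with a warning).
MAPE and MAE are voxel-wise; the default domain is the brain mask (a
whole-grid mode exists) because the percentage error is undefined on zero
background. SSIM follows the standard windowed definition — uniform 7³
window, canonical stabilizers C1=(0.01·L)², C2=(0.03·L)², dynamic range L
inferred from the true volume — with a Gaussian-window option. Voxel-wise
Cohen's d uses the pooled-SD denominator with n_a+n_b−2 degrees of freedom;
zero-pooled-SD voxels map to 0 with a reported count. For tracer-mismatch
settings only the scale-invariant correlation measures are meaningful; the
scale-sensitive metrics should be skipped there.

## Downstream statistics

- **Longitudinal coupling**: REML linear mixed model
  `true_it = β0 + β1·synth_it + b0i + b1i·synth_it + ε_it` with random
  intercepts and slopes. If the random-slope structure is singular the fit
  degrades to a random intercept and is flagged `degenerate`. The optional
  LR test refits by ML against a null with fixed intercept and random
  intercept only (dropping fixed slope, random-slope variance and
  covariance; df = 3) — the exact null is an assumption, since only the
  statistic's degrees of freedom are conventionally reported.
- **Diagnosis classification**: univariate logistic regression on a tau
  summary; held-out ROC-AUC via the midrank Mann-Whitney statistic
  (invariant to monotone transforms of the scores).
- **Steiger's Z** for two dependent correlations sharing one variable,
  using the pooled-correlation (r-bar) covariance correction — the variant
  appropriate when both correlations involve the same outcome (MMSE).
- **BH FDR**: step-up Benjamini-Hochberg (statsmodels), with monotone
  adjusted p-values.
- **Ordinal Braak regression**: proportional-odds cumulative-logit model of
  temporal SUVR on ordered Braak group (BFGS, gtol 1e-10); complete
  separation is flagged rather than hidden.
- **Tertile trajectories**: rank-based tertiles of the synthetic meta-ROI
  (sizes differ by ≤1), then a mixed model of longitudinal cognition on a
  natural-cubic-spline time basis (default 2 interior knots at time
  terciles, automatically reduced when fewer distinct times are observed so
  the per-tertile design stays full rank) interacted with tertile, subject
  random intercept, REML. Pairwise tertile differences are evaluated at the
  last common visit time (configurable) with SE, t and p.

## Problem sizes and numerical choices

Desk-scale experiments use 16³ grids with 8 ROIs, encoder channels (8, 16),
cohorts of 50–100 subjects and ≤ 20 epochs; the full-scale configuration
(128³, 32 ROIs, channels (16, 32, 64, 128)) runs through the identical code
path. The single-phantom overfit sanity run validates on the training
sample itself (explicit `allow_val_overlap`), with dropout disabled.
Instance normalization uses eps 1e-5 and no affine parameters; dropout
defaults to 0.1; PReLU slopes initialize at 0.25; expert-kernel banks use
He-style initialization. All randomness flows from explicit integer seeds
through `numpy.random.Generator`; training, simulation and fold assignment
are bit-reproducible for a fixed seed on one platform.

## Known limitations

- The autodiff engine is single-threaded numpy aside from BLAS matmuls;
  128³ training is possible but slow — the design target is correctness and
  desk-scale experimentation, not GPU-scale throughput.
- The SD head estimates conditional variance by residual regression, which
  is approximately calibrated (tested within a factor of 2) but not a full
  likelihood treatment.
- The LR test's null model and the trajectory contrast's evaluation time are
  conventions, documented above, not uniquely determined by the protocol.
- Phantom MRI carries tau information only through the atrophy term; real
  T1 contrast is far richer, so absolute fidelity numbers on phantoms are
  not comparable to cohort results.
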