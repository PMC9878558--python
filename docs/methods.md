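# Methods

This note records the modeling, numerical and design choices behind
`trfsweep`, in enough detail to audit or extend them.

## 1. Forward model and estimator

Each electrode's signal is modeled as a sum over stimulus features of
the feature regressor convolved with an unknown kernel (the TRF), plus
noise.  The estimator inverts this model by ridge regression on a
time-lagged design matrix.

**Lag convention.**  For a window (tmin, tmax) in ms at sampling rate
`fs`, integer lags run from `floor(tmin·fs/1000)` to
`ceil(tmax·fs/1000)` inclusive; the design column for lag `l` holds
`x[t − l]`, zero-padded at block edges.  Blocks (60-s presentation
segments) are never concatenated, so no lagged sample ever crosses a
block boundary.  At 256 Hz this gives 117 lags for −100–350 ms and 232
for −100–800 ms; the dense 2-feature model therefore has 234
coefficients per electrode and the sparse 3-feature model 696.

**Ridge with an unpenalized intercept.**  The intercept is handled by
centering, which is algebraically identical to including an unpenalized
intercept column in the normal equations (verified in tests against an
explicit dense-inverse oracle to ~1e−15 relative error).  `ridge_solve`
is the raw-matrix primitive; `fit_ridge` wraps it with feature/lag
metadata and returns a `TRFModel`.

**Moment statistics.**  Per-block sufficient statistics
(XᵀX, XᵀY, ΣX, ΣY, ΣY², n) add across blocks, subtract for
leave-one-out, and slice by feature for reduced models.  One symmetric
eigendecomposition of the centered Gram matrix solves all λ values of a
grid at once, and held-out Pearson accuracy is computed exactly from
the held-out unit's moments without forming predictions.  This is what
makes nested leave-one-out over many folds, grid values and data
quantities affordable; the moments path is tested for exact agreement
with the explicit array path.

**Cross-validation.**  The CV unit is a trial (one 60-s block) for
subject-specific analyses, or a subject for generic pooled analyses.
Each outer leave-one-unit-out fold nests an inner leave-one-out loop
over the training units only to select λ from the ascending decade grid
1e−2…1e8 (first argmax, i.e. ties resolve toward weaker shrinkage).
The held-out unit never influences training or λ (tested: randomizing
the held-out response leaves the fold's λ unchanged).

**Noise floors.**  For a held-out unit with k equal-length segments,
every ordered (data segment i, regressor segment j), i ≠ j pairing is
evaluated with the fold's model; the mean over the k(k−1) mismatched
accuracies is subtracted from the matched accuracy.  For trial-level CV
(`attach_trial_noise_floor`), fold k's floor pairs block k's data with
every other block's regressors under fold k's model.  On null cohorts
this centers corrected accuracy at zero (|mean| < 0.01 over 1,280
values in the acceptance run).

**Contributions.**  A feature's contribution is Δr between the full
model and a reduced model excluding it, evaluated on identical folds
(identical units, order and selection protocol; enforced).  In the
generic protocol, full and reduced models consume identical resampling
draws so Δr is a paired quantity.

## 2. Sweep protocols

* Subject-specific: for each subject and quantity q (default grid 3, 4,
  6, 8, 10, 14, 18, 24, 30, 36, 42 min) the chronologically first q
  retained blocks are cross-validated.  Per-block moments are computed
  once per subject and shared across quantities and model variants.
* Generic: for each (n subjects, m minutes) cell — defaults n ∈ {3, 4,
  6, 8, 10, 14, 18, 24, 30, 36, 41}, m ∈ {2, 4, 8}, i.e. 33 cells per
  model — 20 resamples draw n subjects with replacement.  Folds iterate
  over distinct drawn subjects and remove *every* copy of the held-out
  subject from training.  Draws are generated once from the master seed,
  independently of which model consumes them.  Cells where duplicate
  removal leaves < 2 training units are recorded as failures, never
  silently fit.
* ROI averaging: fitting is always all-channel; only stored accuracies,
  contributions and TRFs are averaged over the 13-electrode frontal
  (around Fz) and parietal (around Pz) sensor sets of the 64-channel
  montage.

## 3. Statistics

Accuracies are Fisher z-transformed before parametric testing.  An
Anderson–Darling gate at α = .05 chooses a one-sample t-test when
normality is not rejected and a Wilcoxon signed-rank test otherwise.
No multiple-comparison correction is applied; the choice is recorded in
output metadata.

`min_data_power` bootstraps subject pools (default sizes 2–41, 10,000
draws) and reports, per pool size and α ∈ {.05, .01, .001}, the
smallest quantity at which ≥ 80 % of draws exceed the two-sided t
threshold; −1 marks unattainable cells.  Its RNG contract is
documented (one `default_rng(seed)`; one `integers(0, n_subj,
(n_boot, n))` call per pool size, in order) so an independently written
exhaustive implementation reproduces it exactly — the acceptance suite
does exactly that at n_boot = 200.  Draws whose sample standard
deviation is within round-off of zero (sd ≤ 1e−9·max(1, |mean|)) count
as non-significant: a constant draw's computed sd is ~|mean|·ε, not 0.

`slope_bootstrap` resamples one result per subject count 1,000 times,
fits a line and declares a positive trend when > 95 % of slopes are
positive.  `trf_similarity` correlates two coefficient arrays after
trimming `floor(25 ms · fs / 1000)` samples from each lag-axis end,
where filter/edge artifacts concentrate.

## 4. Synthetic generator

The generator's purpose is to produce cohorts on which estimator
behavior can be validated against known ground truth, with the
statistical structure of continuous-listening EEG:

* **Word events**: renewal process; inter-onset gap = 0.12 s + gamma
  (shape 2) with overall mean 0.32 s (~3 words/s).  Surprisal is
  log-normal (μ = 1, σ = 0.5; right-skewed, positive), word SNR normal
  (0 ± 4 dB).
* **Envelope surrogate**: white noise → 8 Hz low-pass → half-wave
  rectify → low-pass; non-negative with > 95 % of power below 8 Hz.
* **Kernels**: sums of Gabor-like deflections per feature (acoustic
  features early, word-level features with a late ~380–420 ms parietal
  deflection), times a fixed channel topography, tapered to zero at the
  window edges.  A seed jitters centers (±15 ms) and amplitudes (~20 %).
* **Subject variability**: per-subject multiplicative kernel amplitude
  (log-normal, log-SD 0.2) and latency shift (uniform ±20 ms).
* **Noise**: 1/f^α background (α = 1) with a shared-source spatial
  correlation structure (8 sources, mixing weight 0.3), scaled per
  channel so var(signal)/var(noise) equals the requested SNR.

**Band-limited noise (design decision).**  By default the background
noise is confined to the 1–8 Hz analysis band (`NoiseSpec.band_hz`),
i.e. recordings are generated as they stand *after* the pipeline's
band-pass stage, and SNR means the in-band variance ratio.  With
broadband noise at the same nominal ratio, the effective in-band SNR
after filtering is far higher and a single 60-s block already saturates
the estimator, erasing the accuracy-vs-data-quantity behavior the
package exists to study.  Broadband noise remains available
(`band_hz=None`) and the 1–8 Hz Chebyshev-II filter stage is fully
implemented and tested.

**Emulation scope.**  The generator is linear and stationary: no
artifacts, no non-linear auditory transformations, no session effects,
and the envelope is a noise surrogate rather than real speech.  It is
an instrument for validating estimator properties (recovery, trends,
calibration), not a biophysical EEG simulator.

## 5. Preprocessing

The retained conditioning steps are a zero-phase 1–8 Hz band-pass
(minimum-order Chebyshev type-II: ≥ 80 dB below 0.5 Hz and above 9 Hz,
≤ 1 dB passband ripple per pass, applied forward-backward per block),
per-channel z-scoring over the whole recording, and exclusion of each
run's first block.  The classic Hamming-windowed FIR order rule
(`3.3·fs/transition`, rounded up to even; 846 at fs 256 / 1 Hz) is
implemented as the reference design-bookkeeping rule.  Artifact
removal (referencing, interpolation, ICA) is out of scope because the
synthetic data has no such nuisances.

## 6. Problem sizes and acceptance scaling

The stochastic acceptance checks run at 128 Hz with 8 channels on the
dense model — a deliberate scale-down that preserves every protocol
property (lag structure, nested selection, floors) while keeping the
suite minutes-scale on one core.  Kernel recovery runs at the full
256 Hz / 16 channels.  Cohort seeds used by tests and the acceptance
script are fixed study conditions, derived from the script's `--seed`.

## 7. Known numerical details

* Constant held-out series get accuracy 0 with a warning rather than
  NaN.
* Constant-data CV units are skipped with a logged record.
* `ridge_from_moments` clips tiny negative eigenvalues of the centered
  Gram matrix to zero; λ = 0 on singular designs raises.
* The Chebyshev passband gain touches −1 dB exactly at the design
  edges; checks use a 1e−9 dB tolerance.
* Event onsets within half a sample of the recording end clamp to the
  last sample; genuinely out-of-range events raise.
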