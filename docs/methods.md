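# Methods

This note documents the models implemented in `thetamark`, the defaults and
why they were chosen, what the synthetic generator does and does not
emulate, and the numerical decisions a maintainer should know about.

## Signal conditioning

Recordings are a channels × time matrix with a sampling rate, montage and
state tag, and a per-sample artifact mask that all downstream epoching
respects. The conditioning chain is: bipolar re-referencing (sample-wise
first-minus-second difference; cancels common-mode volume conduction), a
1 Hz order-2 Butterworth high-pass, band-stop notches at the mains (50 Hz)
or wireless sensing (40 Hz) frequency and every harmonic below Nyquist, and
polyphase rational-ratio down-sampling (e.g. 1000 → 415 Hz as 83/200).

All filters are applied forward–backward (`sosfiltfilt`), so they are zero
phase — oscillatory peaks are not displaced in time — at the cost of
squaring each filter's magnitude response; the tests assert the squared
analytic response. Notch half-width defaults to ±2 Hz (order 2 per notch);
the width is a free parameter with no canonical value, so it is exposed in
the API.

Artifact rejection is deliberately non-interactive: 1-s windows are masked
when their peak amplitude exceeds 6× the channel's robust (MAD-based) scale
or their log-variance lies more than 5 robust z-units from the across-window
median. A recording with more than 50 % of samples masked is marked
`excluded`, the same cutoff used to drop noisy datasets in perioperative
practice. Operator-guided ICA review is intentionally out of scope — it is
not reproducible — and ocular artifacts in the synthetic data are simply
amplitude outliers, which this policy catches.

## Spectral features

Welch PSD uses non-overlapping 512-sample rectangular windows drawn only
from contiguous unmasked runs; the resolution is fs/512 (0.977 Hz at
500 Hz). Band powers are sums of PSD bins with the bin-centre rule
low ≤ f < high (γ additionally includes the 90 Hz bin); the 12–13, 20–21
and 35–40 Hz gaps stay unassigned. Relative power divides by the summed PSD
over 4–90 Hz — frequencies below 4 Hz are excluded because movement
artifact and the 1/f background dominate there — making the features
invariant to channel amplitude rescaling.

The fixed feature table is 15 columns: BNST and prefrontal relative power
in the five bands, plus the five coherence bands; patients missing any
feature are excluded and listed in the table's metadata.

## Coherence and directed influence

Magnitude-squared coherence is computed per 10-s epoch (epochs overlap
50 %) with Welch's overlapped periodogram (512-sample Hann blocks, 50 %
block overlap), averaged across epochs and scaled to percent. The band
summary is the *mean* MSC over a band's bins: summing raw MSC across bins
would scale with band width and exceed 100 %, so the mean is the reading
that keeps the printed 0–100 scale.

Granger causality fits a bivariate VAR by ordinary least squares pooled
across 4-s windows with 50 % overlap (windowing enforces local
stationarity; lags never cross window boundaries). The order minimises
`BIC(p) = ln det Σ̂(p) + 4p ln N / N` over 1…max_order (default 20 at
500 Hz, i.e. 40 ms of memory); the selected model must have companion-form
spectral radius < 1. Geweke's frequency-domain measure is computed in the
cancellation-free form

    gc(f) = ln(1 + σ²_cond |H_rd(f)|² / (σ_rr |H̃_rr(f)|²)),

where the transfer function is rotated so the driver innovation is
orthogonalised against the receiver, σ²_cond is the partialled driver
innovation variance, and the receiver spectrum splits exactly into
intrinsic + causal parts. The naive "subtract the causal part from S_rr"
form loses all precision near sharp spectral peaks; the ratio form is exact
algebraically and stable numerically. Theta summaries sum bins in
[4, 8) Hz.

Two controls are built in. Permutation: x-windows are re-paired with
shuffled y-windows (destroying cross-channel alignment, preserving each
channel's spectrum), the model is re-fitted at the observed order, and
p = (1 + #{null ≥ obs})/(1 + n_perm). Time reversal: the full pipeline is
re-run on time-reversed signals; genuine lagged influence flips direction,
influence driven by SNR asymmetries does not.

`var_theory` provides the independent ground-truth route: stability,
autocovariances (companion-form Lyapunov equation), time-domain GC via
Levinson–Durbin on the receiver's autocovariance sequence, and closed-form
spectral GC from known coefficients. The estimator is validated against it:
theta-band agreement within 5 % and the spectral-integral identity
(2/fs)∫gc df = time-domain GC within 2 % on a 300-s realisation.

With exactly two analysed signals the pairwise Geweke measure coincides
with the conditional one, so only the pairwise form is implemented.

## Outcome statistics

Improvement is (pre − post)/pre uniformly across scales; DARS is scored so
higher = less anhedonia, hence clinical improvement yields *negative* DARS
values — the sign is retained rather than flipped so that one formula
serves all scales. Responder: HAMD improvement ≥ 0.5; remission: follow-up
HAMD-17 < 8; partial responder: improvement in [0.25, 0.5). Missing
follow-up visits carry the previous horizon forward.

The correlation matrix is two-sided Spearman per (feature, outcome) cell
with Benjamini–Hochberg correction; the FDR family defaults to all features
for one outcome and is recorded in the result. Under the global null with
independent features the probability that any cell in a 15-test family
survives BH is ≈α, which the type-I simulation confirms (≈5–7 % of 1000
null cohorts).

Ridge permutation importance repeats, per iteration: draw a random 3-fold
split, choose the penalty on it by cross-validated error over a log grid
(1e−3…1e3, 13 points), then draw a *second independent* split, fit
per-fold models at the chosen penalty, and record each feature's drop in
pooled held-out R² when that column alone is shuffled in the validation
folds. Selecting the penalty and scoring importance on the same split
leaks — the chance-best model is kept, so shuffling any used feature
"hurts" — and inflates null importances by an order of magnitude; the
two-split scheme removes that bias (residual bias on pure-noise features is
below 0.04 R² across datasets). Features are z-scored per column so one
penalty is comparable across bands. Ridge solutions come from a per-fold
SVD, which yields every penalty at once and is verified against
scikit-learn's `Ridge` to 1e−10. Importances are reported as mean ± SEM
over iterations (default 10 000; tests use 1000).

Note one small-sample reality: with n = 17 and 14 nuisance features, a
nuisance feature occasionally out-correlates the informative one *in the
data*; no importance method can rank the planted feature first on such a
draw. At the default effect calibration (population R² = 0.55) the top-1
recovery rate is ≈87 %; at the strong-slope regime (population R² = 0.75)
it exceeds 95 %, and the recovery guarantees are stated for that regime.

Stepwise selection is forward entry at p < 0.05 with backward removal at
p > 0.10 (conventional defaults); an empty selection is a reported outcome,
not an error. The paired band contrast is the two-sided Wilcoxon
signed-rank test (exact for small n without ties; z from the normal
approximation) with BH across the five bands.

## Behaviour and mediation

The affective task yields 0–100 VAS ratings of positive/neutral/negative
images on valence and arousal (generator default: five ratings per cell).
Negative emotional bias is (mean positive − mean negative)/mean neutral on
arousal, exactly as printed; the score rises when positive images are more
arousing than negative ones, and both readings of the sign are reported in
analysis output. "Neutral-controlled" scores are differences of means
(target − neutral); a ratio was rejected because it is unstable when the
neutral mean is small.

Mediation X → M → Y uses OLS paths a (X→M), b (M→Y|X), c′ (X→Y|M);
indirect = a×b; inference by patient-level (case) resampling with a
bias-corrected percentile bootstrap (default 5000 draws; plain percentile
available). The bias score is not normally distributed, so a rank-based
inverse normal transform with Blom (3/8) offsets is applied to X before
modelling. Two caveats are deliberate: the BC interval of a product of
coefficients is conservative under the complete null (coverage ≈99 % at
nominal 95 % — a well-known property of the a×b sampling distribution, not
a defect), and only X receives the INT because it is the variable the
transform was described for.

## Fiber scoring

E-field volumes are nonnegative magnitude grids with an invertible affine
(2 mm voxels by default); fibers are mm-space polylines. Voxel traversal
uses the Amanatides–Woo digital differential analyzer per segment — exact
segment–voxel intersection, hence invariant to inserting collinear points —
with half-open voxel extents and 0-based indices. A fiber's weight is the
maximal traversed magnitude, absent when no traversed voxel exceeds the
threshold (default strictly > 0). Per-fiber Spearman R against the
per-patient target uses pairwise deletion of absent weights (minimum 4
pairs) and flags significance at unadjusted p < 0.05, as in fiber-filtering
practice; the weighted density map accumulates fiber weights per voxel on
the template grid.

## Longitudinal tracking

Daily alignment averages episodes within (patient, day), collapses all
washout days of a patient to a single averaged point *before*
normalisation, then z-scores theta and HAMD within patient; zero-variance
patients are excluded with a logged reason. Phase contrasts compare
within-patient episode means post-sham vs post-active per band (Wilcoxon,
BH across 5 bands). State correlations pool episodes across patients —
matching the all-episode design — after within-patient centring, so they
reflect state covariation rather than trait offsets; z-scoring was chosen
for the unspecified "normalisation to enable comparison between patients".

## The synthetic generator

One master seed expands per sub-generator via
`SeedSequence([seed, stream])` with fixed stream ids, so an entire study
regenerates bit-identically. Every dataset returns its `GroundTruth`;
no pipeline stage reads it.

- **Coupled recordings**: each channel is an AR(2) oscillator with poles at
  radius 0.97 and 6 Hz; the receiver carries a lag-1 cross term c = 0.4
  from the driver (forward = PFC→BNST). Channels are normalised and 1/f^α
  background (α = 1, amplitude 0.5) is added — the nuisance that motivates
  the 4 Hz floor. Stability is checked with the same companion-radius rule
  the estimator uses. Closed-form GC of the generating model is the oracle
  for the estimator.
- **Cohorts** (n = 17): BNST theta ~ N(8, 2.5²) % is the single informative
  feature; improvement = 0.9 − 0.06·theta + ε with σ_ε = 0.1357, i.e.
  population R² = 0.55 for the univariate theta regression — the
  calibration point for effect size. The other 14 features are independent
  draws. Follow-up scores are derived from the improvement draws and
  clipped to instrument ranges (HAMD 0–52, MADRS 0–60, HAMA 0–56, DARS
  17–85; DARS rises with improvement). The behavioural bias is
  0.9 − 0.08·theta + ε (σ = 0.33), giving a population Spearman of ≈−0.5
  with theta. A "strong slope" regime (σ_ε = 0.0866, population R² = 0.75)
  defines the feature-recovery guarantees. The cohort table is generated at
  the patient level; recordings whose *measured* theta equals the drawn
  value (bisection against the same Welch measurement the pipeline uses)
  are materialised on demand — signal-level simulation of every patient in
  a 1000-cohort null study would be pointlessly expensive, and the
  statistics consume only the table.
- **Mediation triples**: X ~ N(0,1), M = aX + e, Y = c′X + bM + e with
  a = −0.5, b = −0.6, c′ = 0, σ_e = 0.6; indirect = 0.30.
- **Fiber phantoms**: 40³ voxels at 2 mm; one planted fiber runs through a
  Gaussian blob (σ = 5 mm) whose per-patient amplitude is linear in theta
  (plus optional noise); the blob core is background-free so the planted
  weight equals the amplitude exactly, and all other fibers keep ≥16 mm
  from the blob centre so their weights — maxima of a smooth random
  per-patient background — are independent of theta.
- **Episode series**: 10 patients × 11 episodes (8–17 supported) across
  crossover phases; anxiety ~ N(55,15²) clipped to [0,100], mood shares a
  common factor with anxiety (pooled r ≈ 0.37), theta = base_p + 0.5·z_anx
  − 2.0·[post-active] + N(0,1). The effect sizes are sized by analytic
  power to the detection guarantees (state correlation power ≈98 % at
  n = 110; paired theta contrast d ≈ 2 at n ≈ 10). Clinically observed
  state correlations can be weaker (r ≈ 0.2–0.3), where this design would
  be underpowered — the guarantee is about the pipeline, not about effect
  sizes in patients.

What the generator does **not** emulate: volume conduction and shared
reference structure across channels, non-stationary artifacts beyond
amplitude bursts, realistic head geometry or electrode physics (fields are
analytic blobs plus smooth noise), item-level affective structure, or
dropout/missing-visit patterns. Passing tests therefore demonstrate the
correctness and power of the *analysis machinery* under the stated
conditions, not performance on clinical recordings.

## Problem sizes in the validation battery

The test suite and `scripts/acceptance.py` use: 300 s for the GC oracle
(noise-free VAR), 60 s × 100 replicates for direction/time-reversal, 1000
null cohorts for the FDR family rate, 20 runs × 1000 iterations for ridge
recovery, 100 + 500 replicates at 1000 bootstrap draws for mediation, 100
phantoms of 50 fibers × 17 patients, 100 episode-series replicates, and a
reduced end-to-end profile (30 s signals, 50 ridge iterations, 300
bootstrap draws, 12 fibers) for the byte-identity check. These sizes keep
the battery at a few minutes while leaving the Monte-Carlo error of each
rate well below the margin to its threshold.

## Known limitations

- MVAR estimation is OLS on stacked windows, not Levinson–Whittle; the
  asymptotics are identical and the implementation is swappable.
- The GC window length (4 s) follows the stationarity segmentation; the
  model is still estimated on the pooled windows ("universe of data"),
  which is one of two defensible readings.
- Pooled-window permutation is one of several admissible nulls for GC
  significance; it preserves spectra but not slow cross-window trends.
- Per-iteration CV of the ridge penalty (rather than one fixed penalty)
  follows the repeated-CV description; with n = 17 the chosen penalty is
  noisy, which the importance SEM absorbs.
- k-fold importance on 17 patients shares the dataset's spurious
  correlations between folds; generalisation claims across patients are
  explicitly out of scope.
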