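# Methods

## Model and assumptions

The estimator maps per-muscle sEMG envelopes to a scalar force-like target
through an affine function of log envelopes,
`f(t) = w0 + Σ wᵢ ln(sEMGᵢ(t))`. The assumptions this encodes:

- the envelope is a monotone correlate of muscle drive, and the
  drive-to-force map is concave over the operating range (log-like
  saturation rather than proportionality);
- muscle contributions superpose additively at the joint, with antagonists
  entering through negative weights;
- the target is synchronously sampled and free of electromechanical delay
  (both EMG and force are conditioned with zero-lag filters, so neither
  signal is delayed relative to the other; delay estimation is out of
  scope);
- residual error is additive and roughly stationary.

Because the model is linear in its parameters, the fit is an ordinary
least-squares problem: convex, with a unique global optimum whenever the
design has full column rank. No iterative optimiser, learning rate or
initialisation enters the proposed estimator.

## Envelope extraction

EMG is band-pass conditioned (presets: 15–350 Hz for lower-limb bipolar
recordings, 20–450 Hz for upper-limb monopolar grids; both 4th-order
Butterworth), full-wave rectified, and low-pass filtered with a 2nd-order
zero-lag Butterworth at 2.0 Hz — a cutoff suited to slow/quasi-static
contractions. Rectification uses |x| rather than x² because sEMG amplitude
distributions are centrally peaked (Laplacian-like) and the absolute value
has lower variance. "Zero-lag" means forward-backward application of the
stated-order design (squared magnitude response, zero net phase), with
reflective padding of 3·(order+1) samples to suppress startup transients on
short epochs. Low-pass ringing can undershoot zero near sharp onsets; the
envelope is clipped at 0, which the downstream log requires anyway. With
several channels per muscle the per-sample median across channels is the
representative envelope (even counts: mean of the two central order
statistics); a single representative channel can be selected instead, since
the field uses both conventions. The measured force is low-pass filtered at
1 Hz (4th-order, zero-lag).

## Numerical choices

- **Log floor.** ln(0) is undefined, and envelopes touch zero. Envelopes
  are floored at `ε = 1e-8 × (global max envelope)` before the log; the
  relative form keeps the fix independent of amplitude units. The synthetic
  generator uses the same floor, so the generative and fitted model classes
  coincide exactly.
- **Solver.** Full-column-rank systems: economy QR and a triangular solve.
  Rank-deficient systems: SVD pseudo-inverse, taking reciprocals only of
  singular values above `max(N,m)·σmax·eps`, which returns the minimum-norm
  minimiser. The normal-equation product appears only in test oracles. The
  condition number reported with every fit is σmax/σmin of the design —
  equal to the square root of the condition number of AᵀA, which is why the
  solvers avoid the Gram matrix.
- **Detrending.** The intercept column makes explicit mean removal
  redundant; a `detrend` option subtracts the force mean before fitting and
  restores it into `w0` (predictions are identical either way).

## Baseline models

Nine classical per-muscle amplitude-to-force families plus four generic
regressors are implemented for comparison (see the table in
`emgforce/baselines.py`). Fitting recipes:

- **LIP families (1, 5, 6, 8, 9, OLS):** basis expansion + least squares.
  Model 1's duplicated term and the repeated per-muscle intercepts of
  models 6/8/9 make their bases collinear by construction; the minimum-norm
  pseudo-inverse path absorbs the degeneracy rather than reparameterising
  the printed forms.
- **Non-convex families (2, 3, 4, 7):** particle swarm optimisation of the
  estimation-set SSE; 10 independent seeded swarms, returning the restart
  with the lowest validation RMSE. Budget: 200 iterations per weight, swarm
  size min(100, 10·weights), self/social acceleration 1.49, minimum
  neighbourhood fraction 0.25, plus the reference implementation's stall
  termination (20 stall iterations at tolerance 1e-6; set
  `max_stall_iter = max_iter` to exhaust the full budget). Bounds default to
  [−10, 10] for multiplicative/additive coefficients and [−5, 5] for
  exponent parameters; exponentials are clipped at 1e12 (model 3 is known
  to blow up on some data). Model 7 is parsed as
  `env^a + exp(b − c·env)`, the reading consistent with its three
  parameters. PSO families carry no global intercept, as printed. These
  choices are configurable.
- **Ridge (RLS):** λ = 0.01 on the non-intercept weights (penalising the
  intercept would break mean recovery). The objective has a closed form, so
  it is solved directly; no iterative solver is needed.
- **SVR:** linear support-vector regression (scikit-learn), penalty C tuned
  by 5-fold cross-validation over 10⁻³…10³ on the estimation set.
- **ANN:** one hidden layer of 10 tanh units — "ten hidden" units, the
  configuration a damped Gauss-Newton trainer handles at this scale —
  trained by Levenberg-Marquardt (initial damping 0.001, ×/÷10 adaptation
  between Gauss-Newton and steepest-descent regimes), early stopping on the
  validation split (patience 6), up to 3 re-initialised restarts on
  divergence. The hidden width is configurable (`--ann-hidden`).

All baselines regress on raw envelopes; only the proposed model uses the
log transform.

## Data allocation

Contiguous time blocks by default: 50/50 estimation/test for the convex
estimators, 30/20/50 estimation/validation/test for families needing
hyperparameter selection. Contiguous blocks are the default because
consecutive samples are strongly autocorrelated — an interleaved split
would leak the estimation set into the test set; interleaving remains
available as an option.

## Statistics

- Metrics: Pearson r; R² = 1 − SSE/SST with the squared-deviation SST (the
  form under which R² is the coefficient of determination); adjusted R²
  with the model's parameter count; RMSE, MAE. Negative R² is reported, not
  clipped.
- Bland-Altman: residual (predicted − measured) bias, SD and bias ± 1·SD
  limits by default, with `n_sd=1.96` restoring the conventional clinical
  limits; plus the LS regression line of residual on measured signal as a
  variance-homogeneity diagnostic.
- Bias: paired t of residuals against zero; identical inputs return
  t = 0, p = 1 by convention.
- Model comparison: classical one-way within-subject ANOVA (no sphericity
  correction), Bonferroni-adjusted paired t tests against the designated
  reference model. The repeated unit (subject or sample) is the caller's
  choice of score matrix.
- Mann-Whitney U: exact null distribution for small tie-free samples; full
  enumeration over label assignments for small samples with ties (bounded
  by the assignment count C(n, n_a) ≤ 20 000 — the only bound under which
  enumeration is actually feasible); tie-corrected normal approximation
  otherwise.
- ROC: AUC via the rank identity U/(n₁n₀); Youden-optimal cutoff with ties
  broken toward higher specificity. AUC pairs are compared with the
  placement-covariance (DeLong-family) paired z test — the standard choice
  for paired AUC comparison.
- Sample size: smallest N whose overall regression F test reaches the
  requested power, using the noncentral-F convention λ = f²·N with
  f² = R²/(1−R²). Conventions differ across software (some use
  λ = f²·(df_err + k + 1) variants and shift N by ±1); the λ = f²·N form is
  the common default and is documented here because the returned N depends
  on it.
- Shapiro-Wilk normality checking is delegated to scipy.

## Synthetic data

The generator produces what the estimator assumes: per-muscle activation
profiles (ramps to 30/50/70 %MVC over a 5 %MVC resting tone, each muscle's
ramp order rotated and time-shifted so profiles are linearly independent;
sway-like < 0.5 Hz drifts; or constant effort), multiplied by independent
unit-RMS band-limited carriers (band-pass-filtered white noise, Laplacian
by default to match measured sEMG amplitude statistics, Gaussian
optionally), eight channels per muscle, 2048 Hz. The force target is the
log-linear model applied to the true profiles plus white noise with SD
equal to 5% of the force range by default. All generators are
bit-reproducible under a fixed seed, and datasets written to disk carry a
manifest with the true weights — the oracle for recovery tests.

What it does **not** emulate: motor-unit recruitment and firing statistics,
action-potential shapes, amplitude cancellation, crosstalk, electrode
geometry, skin-electrode impedance, or electromechanical delay. Passing
tests therefore demonstrate correctness of the estimation machinery under
the model's own assumptions — not that the log-linear form is adequate for
any particular recording.

Rectification bias makes full-pipeline weight recovery approximate rather
than exact: the extracted envelope is proportional to E|carrier| times the
profile, not the profile itself, so the amplitude scale (and hence `w0`)
shifts while the per-muscle weights and predictions are unaffected —
multiplying any envelope by c > 0 changes only `w0` by `−wᵢ ln c`. Exact
weight equality is therefore asserted only on the generative envelopes;
the full pipeline is judged by held-out prediction R².

## Calibration of the zero-bias check

Testing the mean of test-set residuals with a sample-level paired t within
a single recording is anti-conservative: the fitted intercept carries
estimation error of order σ/√n_est that is common to every test sample,
inflating the variance of the t statistic by (1 + n_test/n_est) — about
16% rejection at a 50/50 split instead of the nominal 5%. The package's
bias experiment therefore works at the subject level: each replicate
simulates several independent recordings, fits per subject, and applies the
paired t across subjects to mean measured vs mean predicted test force.
Under the well-specified generator this null is exact, and the observed
rejection rate sits near the nominal level.

## Problem sizes and runtime

The test suite and the acceptance script run on deliberately modest problem
sizes — 4–8 s recordings at 2048 Hz (8–16 k samples), 2–4 muscles, PSO on
systems of 2–10 weights, 100-replicate calibration runs on
profile-plus-noise data (skipping carrier synthesis where the carrier is
irrelevant to the quantity measured). These sizes are large enough for
every asserted property to be sharp (LS recovery is exact at any size;
Monte-Carlo bands use 20–100 replicates) while keeping a full run on one
CPU in tens of seconds. A single 250 ms epoch (512 samples, 4 muscles) fits
in well under a millisecond, which is the real-time feasibility claim the
timing check asserts.

## Known limitations

- Envelope extraction, not the LS solve, dominates pipeline cost; the
  2 Hz zero-lag filter is non-causal, so a real-time deployment must
  substitute causal filtering (and accept its group delay) for both EMG and
  force paths.
- The PSO implementation follows the MATLAB-style adaptive-neighbourhood
  variant; other PSO variants will reach different (possibly better) local
  minima on the non-convex families. Its purpose here is comparison, not
  state-of-the-art global optimisation.
- The rm-ANOVA applies no sphericity correction; with few subjects and many
  models its p-values are approximate.
- The sample-size routine covers only the overall F test of a multiple
  regression (effect size f²), not tests of individual coefficients.
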