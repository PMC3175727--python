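# Methods

This note records the modelling assumptions, parameter choices and numerical
conventions behind `p300speller`, and what the simulation-based tests do and
do not establish about real EEG.

## Signal model of the simulator

A simulated session is the superposition of three parts, per channel, in
microvolts:

1. **Event-related templates.**  Every stimulus whose type matches the
   attended row or column adds a target-specific deflection at its onset:
   a positive Gaussian bump (default amplitude 5 µV at Pz, latency 300 ms,
   width σ = 55 ms) and a negative bump (default −3 µV, latency 200 ms,
   σ = 40 ms).  Real ERPs are not Gaussian; the bump parametrisation was
   chosen because amplitude, latency and width are exactly the three
   properties the downstream pipeline is sensitive to, and because no
   published functional form exists to copy.  Channel topographies are
   fixed gain vectors: the positive component peaks centro-parietally
   (Pz = 1.0, falling to 0.75 at Cz), the negative component is
   posterior-weighted (PO3/POz/PO4 = 1.0, falling to 0.2 at Cz) —
   consistent with a component that remains informative under covert
   attention.  Nontarget stimuli add nothing event-specific.
2. **Stimulation-rate oscillation.**  A continuous 5 Hz sinusoid (default
   1 µV) phase-locked to the stimulus train; all onsets fall on multiples
   of the 200 ms stimulus period, so every epoch sees the same phase, as a
   real trial-averaged waveform does.
3. **Background noise.**  Independent per-channel stationary AR(2) noise,
   x_t = 1.7 x_{t−1} − 0.72 x_{t−2} + ε_t, with innovations scaled
   analytically so that the *marginal* standard deviation equals
   `noise_std`.  The poles (0.9 and 0.8) give a strongly low-passed,
   EEG-like spectrum; white noise would be implausible and would also make
   the 0.5–15 Hz band-pass a near-no-op.  A 2000-sample burn-in is
   discarded so the series is effectively stationary.

Timing: 100 ms intensification + 100 ms gap (12 stimuli per trial, each
type exactly once per trial, order uniformly random per trial), trials of a
character back to back, 1 s pre-session padding and 1 s between characters.
The inter-character pause and padding are implementation constants (they
only need to exceed the epoch length).

All randomness derives from a single integer seed through splittable
`SeedSequence` streams (schedule, per-channel noise), so every artefact is
bit-reproducible.

**SNR personas.**  `high` (6/−4 µV components, 4 µV noise), `medium`
(5/−3, 10) and `low` (3.5/−2, 20) qualitatively span near-ceiling decoding
at k ≈ 10, comfortable decoding at k = 15, and ~40–50% accuracy at k = 15
respectively.  They are illustrative operating points, not calibrations to
any individual: per-patient SNR is not recoverable from published accuracy
curves.

**What the simulator does not model:** eye movements, EMG/EOG artefacts,
channel-to-channel noise correlation, latency jitter or habituation of the
ERP, transmission losses.  Tests that pass on this generator therefore
certify the *pipeline* (filtering, featurization, training-set
construction, classifier implementations, decoding and evaluation
arithmetic), not clinical performance; absolute accuracies on real patient
EEG, and the relative ranking of classifiers on it, are outside what the
synthetic benchmark can establish.

## Preprocessing conventions

- Band-pass 0.5–15 Hz, Butterworth of design order 4, applied forward and
  backward (`sosfiltfilt`) to the **continuous** recording before cutting —
  zero phase, squared magnitude response, no per-epoch edge transients.
- Epochs are 1000 ms from stimulus onset; downsampling keeps samples
  0, 25, 50, …, 975 (0-based, onset sample included), i.e. 40 Hz.
- Features are the amplitudes at 100, 125, …, 750 ms, **endpoints
  inclusive** (27 instants per channel, N = 216 for the default montage),
  concatenated channel-major.  Inclusivity at both ends is a convention
  choice; it is held in one constant and asserted in the tests.
- Z-scoring statistics (mean, population std) are computed over the union
  of both classes of the *averaged-response* training set — the objects the
  classifiers actually consume — and reused unchanged at test time.
  A feature whose training std is at rounding-error level raises
  `DegenerateFeatureError` rather than being silently dropped, so feature
  indices stay aligned across classifiers.
- Each averaged training example draws its k single-stimulus responses
  without replacement; the 1000 examples per class are drawn independently
  (with replacement across examples), since far more averages are requested
  than the ~110–220 single responses that exist.  Averaging is performed on
  per-epoch feature vectors; this is bit-identical to averaging raw epochs
  first because downsampling, instant selection and averaging are linear.
- One normalization + classifier is fitted per k (training averages match
  the testing average depth); `refit_per_k=False` reuses a single k=15
  model for sensitivity analysis.

## Classifier notes

- **Fisher LDA** uses per-class sample covariances (ddof = 1) summed, with
  a trace-scaled ridge (1e−6 × mean eigenvalue) added only if the Cholesky
  factorization fails.  The bias centres the balanced training set.
- **Stepwise LDA** uses the classical regression construction on ±1
  labels: forward entry by the smallest partial-F p-value (< 0.1), backward
  removal by the largest coefficient t-test p-value (> 0.15), iterated to
  convergence or 60 features; ties break to the lower feature index, and
  numerically collinear candidates can never enter (so exactly one of a
  duplicated pair is retained).  Final weights are OLS on the retained set.
- **Bayesian LDA** is exact ridge regression at fixed (α, σ²) — verified
  against an independent linear solve to 1e−8 — with hyperparameters from
  the evidence fixed point: ν = Σ λᵢ/(λᵢ + σ²α) over eigenvalues of FᵀF,
  α ← ν/‖μ‖², σ² ← ‖t − Fμ‖²/(n − ν); tolerance 1e−6 on the relative
  change, at most 500 iterations, non-convergence raised with the full
  iteration trace attached.  When the labels carry no information the fixed
  point sends α to infinity geometrically (all weights → 0); hitting the
  α ≤ 1e10 bound is treated as the converged no-signal limit.  The model
  accepts arbitrary real targets (it is a regression network); ±1 labels
  are simply its speller use case.
- **Linear LS-SVM** is solved in the condensed primal: because labels are
  ±1, the equality-constrained problem min ½‖w‖² + γΣeᵢ² s.t.
  yᵢ(wᵀfᵢ + b) = 1 − eᵢ reduces to ridge regression of y on [X | 1] with
  penalty 1/(2γ) on w only.  The tests verify equality (1e−6) with the
  dual KKT system solved independently.  γ is line-searched over
  10⁻³…10³ in half-decade steps by stratified 5-fold CV accuracy, ties to
  the smaller γ.
- **Kernel SVM** delegates the per-point QP to `sklearn.svm.SVC` and owns
  the grid search: C ∈ 2⁻⁵…2¹⁶, γ ∈ 2⁻¹⁵…2⁶ (ratio 2³, 8 × 8 = 64 pairs),
  stratified seeded 5-fold CV, ties to smaller C then smaller γ, winner
  refitted on all data.
- **Feature-extraction projection** maximizes
  I(Y, C) = Σ_p p(t_p)(J(Y|t_p) − log σ(Y|t_p)) − J(Y) with the robust
  two-term negentropy contrast (k₁ = 36/(8√3 − 9), k₂ = 24/(16√3 − 27)).
  The estimator is evaluated on projections normalized to unit overall
  variance: the identity H(Y) = H_gauss(σ(Y)) − J(Y) makes the expression
  above exact only at σ(Y) = 1, and without the normalization the
  criterion would reward minimum-variance directions regardless of the
  labels (observed in practice as convergence to pure-noise directions).
  Optimization is projected gradient ascent on the unit sphere with
  backtracking (20 random restarts, forward-difference gradient batched
  through precomputed projections); the sign of w is fixed so targets
  project positively, and a `low_information_` flag marks objectives below
  1e−2 (classes indistinguishable along any direction found).  Tests pin
  the optimum to a 360-direction grid oracle within 1° on 2-D problems.
- **Neural network** y(f) = Σᵢ w²ᵢ F(Σⱼ w¹ⱼᵢ fⱼ + bᵢ) + b with the
  decreasing sigmoid F(t) = 1/(1 + e^t), trained toward ±1 targets by a
  trust-region Gauss–Newton least-squares optimizer with an analytic
  Jacobian (`scipy.optimize.least_squares`, `trf`/`lsmr`).  A pure
  Levenberg–Marquardt step requires at least as many residuals as
  parameters, which fails for M near 20 at N = 216; the trust-region
  variant satisfies the same sum-of-squares contract without that
  restriction.  M is line-searched over 1…20 by stratified 5-fold CV
  (ties to smaller M), the winner retrained on all data; diverged fits are
  retried with fresh initializations.

## Evaluation machinery

- Accuracy at k uses every k-combination of the 15 recorded trials per
  character, enumerated exhaustively up to `max_combinations` (default
  5000, i.e. exhaustive for all k at 15 trials except k = 7 and 8) and
  uniformly subsampled above it.  Subset averaging is an indicator-matrix
  product, so a full 36-character × C(15,10) = 108 108-decode sweep takes
  seconds with a linear model.
- Error grids are 11 × 11 percentage histograms of typed-minus-intended
  (row, column) offsets; the centre cell equals the accuracy at that k by
  construction (asserted).  Directional dispersion is the **population**
  standard deviation (divide by n) of the row and column offsets.
- The windowed-feature analysis restricts the feature set to the instants
  within ±25 ms of each window centre (2–3 instants per channel on the
  25 ms grid), refits normalization and classifier, and decodes at k = 15
  from the single full 15-trial average.
- Chance level is 100/(rows × columns) = 100/36 ≈ 2.78% for the default
  layout.
- Decoding ties (equal scores) resolve to the lowest row/column index — a
  measure-zero event on real scores, made deterministic for degenerate
  inputs.
- Significance testing of method × k effects (repeated-measures ANOVA and
  post-hoc pairwise comparisons) is intentionally not reimplemented: the
  per-k, per-method accuracy and dispersion tables are exported as tidy
  structures for standard statistical software.

## Problem sizes in the shipped tests and acceptance script

The test suite and `scripts/acceptance.py` run the same code paths the
package exposes, at desk-scale problem sizes chosen for tight feedback
loops: 6–36 test characters per session, 120–200 averaged responses per
class where a classifier is fitted many times (the full 1000 per class is
exercised where only one fit is needed), and capped combination counts for
k = 7 and 8.  The zero-ERP chance-level control keeps the full
36 × C(15,10) sweep.  Statistical assertions use binomial bands at
α = 0.01 built on the number of *independent* units (e.g. 36 characters,
not 108 108 correlated subset decodes).

## Known limitations

- Gaussian bumps cannot probe sensitivity to ERP asymmetry or latency
  jitter; a flat-topography positive component plus fixed posterior N2 is a
  coarse stand-in for subject variability.
- The FE and NN classifiers are the slowest by two orders of magnitude
  (restarts × finite-difference gradients; CV over 20 architectures) —
  consistent with their role as comparison baselines rather than
  recommended decoders.
- EDF files can be read (via mne) but sessions are persisted as CSV/JSON;
  EDF export is not provided.
- No online/closed-loop operation, feedback rendering, error-potential
  correction or alternative stimulation paradigms.
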