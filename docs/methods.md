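# Methods

This note records the models, parameter choices and numerical decisions
behind `eegtwin`, and what the synthetic benchmark does and does not
establish.

## Synthetic motor-imagery model

Each trial of subject `s` is

    x_c(t) = n_c(t) + a_{k,c} · r_c(t),

with `n_c` Gaussian background noise shaped to a `1/f^γ` power spectrum
(default γ = 1, amplitude 10 µV SD — nominal microvolts; absolute scale is
irrelevant to CSP and the SVMs but fixed for readability) and `r_c` a
unit-variance stochastic oscillation confined to the subject's informative
band.  That band is the configured band (default 8–12 Hz) shifted by a
per-subject draw uniform in ±`band_jitter` (default 2 Hz), which is what
gives adaptive band selection something real to find.  The rhythm is
band-limited filtered white noise, not a sinusoid, so trial covariances
fluctuate realistically.

Channels are assigned round-robin to one designated group per class, which
makes the expected CSP filter direction checkable.  The amplitude map is

    a_{k,c} = A · sqrt(1 − erd_depth)   if channel c is in class k's group
            = A                          otherwise,

so the class effect is multiplicative on band *power*, emulating
event-related desynchronization.  `A` is set to 10× the in-band background
SD: the rhythm then carries ≈99% of the in-band power, and the measured
class-conditional band-power ratio tracks `1 − erd_depth` to within a few
percent (the tests require 10% at ≥100 trials).  This is deliberately a
high-SNR world; the weaker, non-stationary rhythms of real EEG are emulated
only through `erd_depth` (a cohort of heterogeneous depths stands in for
good and poor performers).

Ocular artifacts are raised-cosine pulses of 0.5 s (spectral content below
4 Hz), peak 20 µV × `gain`, mixed into the two most frontal channels with
weights 1 and 0.5 at random positions in a configurable fraction of trials.
When the generator injects artifacts it also appends a recorded "EOG"
channel (artifact + 0.5 µV sensor noise), because regression-based removal
needs a measured reference, exactly as in practice.

Not modelled: volume conduction / realistic forward models, within-trial
non-stationarity, mains interference, inter-channel background correlation.
A green pipeline test therefore establishes correct information flow and
sensitivity at the stated SNR, not performance on any particular public
recording.

Determinism: every function takes explicit seeds; subject `i` under master
seed `s` uses `SeedSequence([s, i])`, so outputs are bit-identical across
runs and machines with the same numpy/scipy versions.

## Preprocessing

Band-pass filtering is a 4th-order Butterworth applied forward-backward
(`sosfiltfilt`, reflective padding), i.e. zero phase — the de facto standard
before covariance-based spatial filtering.  Epochs shorter than the filter
warm-up are rejected with an explanatory error.  RMS-based assertions in the
tests exclude the first/last 0.25 s to avoid edge transients.

Artifact removal is per-trial ordinary least squares of each data channel
on the reference channel(s); the fitted contribution is subtracted and the
reference channels are dropped.  Re-estimating coefficients each trial is
the "adaptive" element; it also removes whatever genuine signal is linearly
correlated with the reference within the trial — the price of regression
methods generally.  A reference that is identically zero in a trial is
skipped (coefficient 0) and logged.  ICA-style removal is out of scope.

## CSP

Per class, trial covariances are trace-normalized, averaged, and shrunk
toward `(tr C / d) I` by `regularization` (default 0.05 — small-sample
stability; 0 is allowed but rank-deficient composites are then rejected
with advice to raise it).  Filters solve `C₁ w = λ (C₁+C₂) w`; scipy's
`eigh` normalization gives `Wᵀ(C₁+C₂)W = I` directly.  `n_components`
(default 4) filters are taken half from each end of the spectrum.  Features
are `log(var_i / Σ var_j)` over retained components — scale-invariant, and
the log symmetrizes the two classes' feature distributions.  A
zero-variance component is floored at the smallest positive double before
the log.

Band selection runs stratified k-fold CV of the downstream classifier on
each band's features and returns the argmax, ties broken toward the
lower-frequency band for reproducibility.  In the full pipeline both CSP
fitting and band selection happen inside each outer training fold, so the
reported accuracy is leakage-free (this is verified by a label-poisoning
audit test).  Only one band's features are used per fold — strict selection,
not cross-band concatenation.

## Classifiers

*Soft-margin SVM* (`min ½‖w‖² + λ Σξ`) is delegated to libsvm via
scikit-learn (tol 1e−8, iteration cap 10⁶) behind the `train_svm` surface;
slack values are recomputed from the margins and reported.  An independent
SLSQP quadratic-programming oracle on the dual verifies the objective to
1e−6 in the tests.  Note that the 0/1 *training error* is not monotone in λ
(only the optimal total slack is); the tests assert the provable statement.

*TWSVM* duals are box-constrained QPs `min ½αᵀQα − eᵀα, 0 ≤ α ≤ c` with
`Q = G (HᵀH + εI)⁻¹ Gᵀ`, solved by projected L-BFGS-B with analytic
gradients (ftol 1e−15).  *LS-TWSVM* solves the two SPD systems given in the
README with ridge ε = 1e−8; a singular system raises with advice to raise
the ridge.  Kernel models expand the planes over the full training set (no
reduced-set approximation); plane distances are normalized by the
kernel-space norm `sqrt(wᵀ K w)`.

One caveat worth recording: on *perfectly symmetric* cross-shaped data
(each class's cloud straddling the other's ideal plane), the TWSVM optimum
is degenerate — `w = 0, b = −1` satisfies every constraint with zero hinge —
so no solver recovers the axes there.  The classic cross-data advantage of
twin methods holds when the arms are sampled asymmetrically about the
crossing point, which is how the tests (and `examples/03`) construct it.

Conventions, fixed for reproducibility: plane 1 belongs to class +1; exact
distance ties predict +1; multiclass is one-vs-one with majority vote, vote
ties broken by summed signed plane-distance margins, then by the lower
class index.  Binary routines require labels exactly {+1, −1}.  Fitted
binary models serialize to a JSON container with a round-trip guarantee.

*Baselines*: LDA is the two-class Fisher discriminant with pooled covariance
(ridge 1e−6).  The PNN is a Parzen-window classifier with a Gaussian kernel
of fixed bandwidth; priors are equal by default, with empirical
(count-weighted) priors available — only under empirical priors does the
very-large-bandwidth limit degenerate to the majority class.

## Optimizers

All four maximize a fitness over a bounded box; log-scaled dimensions are
searched in log coordinates.  Defaults (from the reference evaluation
setup): 300 iterations; GA/QGA population 40, 20 bits per encoded
dimension, generation gap 0.95, crossover 0.7, mutation 0.01; QGA rotation
angle 0.01 rad; PSO/CPSO population 20, acceleration constants 1.5 and
1.70.  Unstated details were fixed as: PSO inertia decaying linearly
0.9 → 0.4 (the canonical schedule), velocities clamped to half the box;
CPSO chaotic sequences from the logistic map with r = 4 (initialization
replaces uniform draws; each iteration the global best is perturbed with a
linearly shrinking radius and the perturbation kept only if fitter); GA
roulette selection with elitist reinsertion of offspring over the worst
individuals; QGA qubits initialized to equal superposition (α = β = 1/√2),
measured by amplitude-squared sampling, updated by a rotation gate of fixed
magnitude whose sign steers each qubit toward the best-so-far bitstring
(quadrant-aware standard lookup).  "Quantum crossover/interference" are
names without definitions in the source description; only measurement +
rotation update are implemented.  Best-so-far traces are non-decreasing by
construction and all optimizers are bit-reproducible under a fixed seed.

The classifier search space is `c₁, c₂ ∈ [2⁻⁸, 2⁸]` and rbf
`γ ∈ [2⁻¹⁰, 2⁴]`, log-scaled — standard SVM tuning ranges.  The fitness for
classifier tuning is stratified 10-fold CV accuracy on the training folds
(`cv_fitness`), the fold count reduced automatically if a class is smaller
than the fold count.

## Evaluation

`run_pipeline` reports held-out accuracy under stratified outer CV (default
10-fold); artifact removal is per-trial (no cross-trial statistics), so it
may run before splitting without leakage, while CSP, band selection and
hyperparameter tuning are refit per training fold.  `compare_methods`
evaluates several methods on identical splits per subject (paired
comparison) and summarizes columns with mean, sample SD (n−1) and
SE = SD/√n.  Both SD and SE are always emitted because published tables are
inconsistent about which the "SE" row actually contains; the reference
table this layout mirrors prints an "SE" row matching neither statistic of
its own printed cells (see the decisions in the test suite), so the
discrepancy is documented rather than reconciled.  Accuracies are reported
in percent, rounded to two decimals in the rendered table only.

Scaled-down budgets: tests and the acceptance script run the tuning loop
with small PSO budgets (≈6 particles, ≤8 iterations, 3-fold inner fitness)
instead of 300 × 20; the full-scale settings remain the defaults and the
300-iteration budget is exercised on analytic test functions, where it is
cheap.  The back-propagation network column of the reference table layout
is not reimplemented (topology unspecified); the report format accepts
externally supplied columns.

## Known limitations

- The EDF reader is omitted (no EDF library in the target environment);
  ingest via `eegtwin.io` containers instead.
- Kernel TWSVM/LS-TWSVM are O(n²)–O(n³) in training-set size (full kernel
  expansion); intended for the few-hundred-trial regime.
- The synthetic world is high-SNR and stationary; absolute accuracies on it
  do not predict accuracies on real recordings.
- PNN distances use a single isotropic bandwidth; features should be on
  comparable scales (CSP log-variance features are).
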