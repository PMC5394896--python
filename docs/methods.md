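# Methods

## The analysis model

All inference is performed at the group level: for each time bin, trials
from all subjects are concatenated and modelled with fixed per-subject
intercepts.  This is deliberate — in the emulated design the perceptual
cue features (fill, color) are *perfectly* confounded with the reward
features (mean, variability) within any single subject, and only the
counterbalancing of cue–reward mappings across subjects renders them
orthogonal in the pooled sample.  Per-subject models are therefore never
fitted.

Because subject intercepts are the only nuisance terms, every model is
computed on subject-demeaned variables, with degrees of freedom reduced
by the number of subjects.  The encoding MANOVA tests the stimulus-
feature term of X ~ Y + S on the F-transformed Pillai–Bartlett trace
(standard F approximation; for hypothesis df q = 1 this reduces to
F = (V/(1−V))·(n−s−p)/p with p channels, s subjects).  The decoding
ANOVA tests the channel block of Y ~ X + S.  For a single numeric
feature the two statistics coincide algebraically — both equal the R² of
the demeaned feature on the demeaned channel space, F-transformed with
identical df — which the cluster-permutation fast path exploits; the two
model surfaces are kept separate because their *channel-contribution*
tests differ, and that difference is what the causal labelling uses.

### Feature coding

Mean reward and variability enter as numeric single-df covariates using
their level values (1, 2, 3 £; 0.08, 0.16, 0.24), mirroring the decoding
model's scalar prediction target; the encoding model is kept symmetric
to it.  `fit_encoding` accepts a multi-column Y for categorical coding,
but numeric is the default throughout the pipeline.

### Causal labels

With α = 0.05 and an indeterminate band (0.05, 0.10]:
encoding-significant ∧ decoding-significant → direct; encoding only →
indirect (band → possible_direct); decoding only → context (band →
possible_direct); neither → undetermined.  Significance is strict
(p < α); p = α counts as non-significant and p = 0.10 falls inside the
band.  Channels are labelled only in bins where the multivariate model
survives cluster correction.

### Cluster-level permutation

Cluster statistic: mass (sum of per-bin F) over maximal runs of bins
with p below the cluster-forming threshold (0.05).  The null permutes
trial labels *within subject* — preserving the subject-intercept
structure, which is the exchangeability the group model assumes — and
records the maximum cluster mass per permutation; cluster p-values use
add-one smoothing, making the test slightly conservative at small
permutation counts.  Cluster-forming threshold and statistic are
configurable (the choice of mass over extent is a convention, not a
finding).  Constant feature labels raise an error rather than returning
a degenerate p.

### Temporal generalization

"Explained variance in the target data" is defined as the multivariate
R² = 1 − SSR/SST pooled over channels about subject means; it is
negative when a transferred model mispredicts.  Subject intercepts are
refitted at the target bin — only the feature pattern is transferred.
Per-entry significance uses within-subject trial-label permutations of
the target data (one batch of permutations reused across target bins);
entries with p > 0.05 or negative explained variance are zeroed.

Two properties of this matrix are worth knowing:

- The *diagonal* is the in-bin (trained) fit.  It sits above its own
  permutation null even for pure-noise data, so calibration statements
  ("≥95 % of entries zeroed under the null") apply to the off-diagonal
  entries; at 200 bins the diagonal is 0.5 % of the matrix.
- Row normalization by the source-bin fit is only meaningful where the
  source model genuinely fits: rows are normalized only if their
  thresholded diagonal is positive, and left zero (and flagged)
  otherwise.  Even so, rows on an onset ramp — significant but small
  in-bin fits — normalize to large values wherever the target signal is
  stronger, so the normalized statistic should be read qualitatively
  (does the stability conclusion survive?), not compared in magnitude
  to the raw one.

The stability statistic sums off-diagonal thresholded entries whose
source *and* target bins lie in the second half-window and subtracts the
first-half block; the null permutes the matrix's time labels jointly
over rows and columns (default 100 000 draws, chunked; the same
machinery is applied to the diagonal to score encoding strength).  The
default test is one-sided (greater), matching the directional question.

### Variability metrics and AIC

SD (= CV·mean) and variance (= SD²) are decorrelated from mean reward by
subtracting their mean within each mean-reward level; the result is
exactly orthogonal to any function of mean level, and the operation is
idempotent.  AIC is computed from residual sums of squares in the
Gaussian form n·ln(RSS/n) + 2k with the additive constant omitted;
differences are therefore exact.  For pooled multivariate models the
bookkeeping is N = trials × channels and k = channels × (subjects + 1) —
identical across compared metrics, so the parameter term cancels and
only RSS differences matter.  A preference (between metrics, or between
mean-reward and variability predictors per channel) is declared only
when the summed |ΔAIC| exceeds 3.  The bin set entering the sum is
configurable; the comparison functions default to all bins, and the
caller can pass the cluster-significant bins.

### Utility estimation

Exponential utility u(c) = (1 − e^(−ca))/a, evaluated via expm1/log1p to
avoid cancellation, with the linear limit u(c) = c for |a| ≤ 1e−8.  The
certainty equivalent of a lottery solves u(c*) = E[u(outcome)] in closed
form.  Risk sensitivity is fitted per subject by least squares on the
certainty equivalents (their natural scale), using bounded 1-D
minimization with multistart at {−1, −0.1, 0, 0.1, 1} over a ∈ [−5, 5]
per £; the exponential-utility model (k = 1) is compared by AIC against
the zero-parameter expected-value model, and a one-sample t test of â
against 0 summarises the group.  On noiseless fixtures the RSS is
floored at n·10⁻²⁴ so the AIC stays finite; the floor cancels whenever
both models fit perfectly, leaving the 2k penalty to decide.

## The synthetic-data generator

The generator emulates the statistical structure of the target design,
not its biophysics.  Defaults are the study conditions: 18 subjects,
450 trials each, the 3 × 3 factorial above, 13 channels (source-level
configuration), 200 Hz over the 0–2000 ms anticipation window, 2.9 %
incorrect responses, and onset latencies anchored to the source-level
values (fill 110 ms, color 130 ms, mean reward 250 ms, variability
540 ms).

Counterbalancing uses two mappings per perceptual feature (identity and
reversed, the middle level fixed), split evenly across subjects — hence
the requirement of an even subject count.  Within every subject the
fill↔mean correlation is exactly ±1; pooled over the balanced group it
is exactly 0.

Channel roles: a *direct* channel adds amplitude × pattern(t) ×
ramp(t − onset) × centred feature value; an *indirect* channel is
gain × (realized direct channel, noise included) + private noise; a
*context* channel loads on the shared brain-state component only.  The
brain state is a smooth per-trial process — white noise smoothed to a
50 ms correlation time, unit variance, gated on at cue onset so baseline
windows stay clean.  A time-varying (rather than per-trial constant)
state matters: a constant's chance correlation with the feature would
contaminate every bin coherently, whereas a process decorrelates across
bins, as slow physiological fluctuations do.  Representational drift is
a spherical interpolation of the direct-channel pattern between two
random unit vectors across the epoch, frozen after the midpoint when
stability emulation is on — the simplest mechanism that yields the
asymmetric cross-prediction matrix.

What the generator does **not** emulate: field spread/leakage between
sensors, autocorrelated sensor noise, eye/muscle artifacts, evoked
transients unrelated to the stimulus features, non-linear or saturating
responses, and between-subject latency differences.  Passing tests
therefore demonstrate that the *statistical machinery* is correct and
calibrated under its own assumptions, not that those assumptions hold
for any particular real recording.

Reward outcome sets use the symmetric 3-point construction
{m − δ, m, m + δ} with δ = cv·m·√(3/2) and uniform probabilities, which
reproduces the requested mean and CV exactly and keeps all outcomes
positive for every cue in the default design (the largest δ is ≈ 0.88
at £3, CV 0.24).

## Preprocessing conventions

- Jump (sensor-reset) artifacts: a first difference strictly exceeding
  3000 fT-like units; correction median-filters the difference series
  (window 21 samples, reflect padding) and reintegrates, and is applied
  only when jumps are detected — which makes it idempotent.
- Amplitude screening flags trials with any |value| above threshold
  (strictly).
- Low-pass: first-order Butterworth, single forward pass by default
  (the filter order is part of the emulated pipeline); zero-phase
  filtfilt is available as an option.  Baseline correction subtracts
  the per-trial, per-channel mean over a half-open window; the
  post-correction baseline mean is zero to machine precision.
  Down-sampling keeps every k-th sample after filtering (the low-pass
  doubles as the anti-alias filter); non-integer factors are an error.
- Bins are left-closed, right-open [t, t + w) with centers at t + w/2;
  indivisible windows are an error stating the remainder.  A trial
  flagged for several exclusion reasons is removed once but counted
  under each reason.

## Problem sizes used by the tests and the acceptance script

Simulation studies run at reduced scale, chosen so each check retains
the power it needs: calibration suites use 4 subjects × 36 trials,
4 channels, 12 bins (200 datasets for cluster family-wise error, 200
permutations each); recovery suites use 6 subjects × 54 trials with
6 channels and 12–24 bins of 20 ms (100 replicates for channel-role
recovery, 40 for temporal stability at 150 trial-label and 1500
time-label permutations, 50 for metric recovery).  The acceptance
script uses the same generators at 20–100 replicates and prints rates
on a 0–100 scale.  Full-scale defaults (1000 trial-label and 100 000
time-label permutations) remain the package defaults.

## Known limitations

- The cluster test assumes within-subject exchangeability of trial
  labels; designs with strong trial-order effects would violate it.
- The group model uses fixed subject intercepts, not random effects;
  inference is conditional on the sampled subjects.
- Cross-prediction transfers patterns between bins of the *same*
  dataset; it does not implement decoder-direction temporal
  generalization.
- AIC comparisons assume Gaussian residuals with a common variance per
  model; heavy-tailed noise would distort the evidence scale.
- The utility fit treats certainty equivalents as exchangeable across
  cues with homoscedastic elicitation noise.
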