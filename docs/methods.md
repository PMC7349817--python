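# Methods

This note documents the models behind `stressband`, the defaults that
matter, what the simulator does and does not emulate, and the design
choices made where the design was genuinely open.

## Heart-rate variability

**Artifact rule.** The percentage rule compares each inter-beat interval
with a local average and flags deviations above a threshold (default
0.20, the common choice in the HRV literature). "Local average" is
implemented as the median of the 5 nearest *preceding accepted* intervals,
a causal, Kubios-style robust variant: because flagged intervals never
enter the reference, a run of consecutive ectopic beats cannot drag the
reference toward itself (a plain running mean fails exactly there; the
unit suite exercises this case). The first interval has no history and is
always accepted. Both threshold and window are configurable
(`ArtifactRuleConfig`).

**Correction.** Flagged tachogram points are deleted and re-evaluated at
their beat times from a cubic spline through the accepted points.
Unflagged beats keep their number, position and value. Series with more
than 50% flagged intervals, and segments with fewer than 30 beats or more
than 50% interpolated intervals, are treated as unusable and dropped —
the upstream description is silent on minimum data quality, so these are
package choices, chosen conservatively.

**Segmentation.** 120-s windows stepping by 60 s (50% overlap), aligned
to the recording start; a trailing partial window is discarded. A 600-s
recording therefore yields exactly 9 segments.

**Features.** Time-domain features use the plain formulas on the interval
list; `std_rr`/`sdsd` use the sample (n−1) denominator (configurable via
`ddof`), pNN50 counts successive differences strictly exceeding 50 ms.
Geometric features histogram the intervals on a fixed 1/128-s grid; the
triangular index is N over the modal count (ties broken toward the lower
bin) and TINN is the base of the least-squares triangle found by
exhaustive search over bin centers, with two empty guard bins on each
side so the base can extend past the occupied range; a single-bin
histogram returns TINN = 0. Frequency features cubic-spline the tachogram
onto a uniform 4-Hz grid, remove a linear trend, and take a single
Hann-tapered periodogram; band powers are integrated spectral density
(ms²) over VLF/LF/HF and pLF/pHF are the in-band peak frequencies. The
taper, detrend mode and resampling rate are exposed because the source
workflow specifies only "FFT"; a boxcar taper reduces the estimator to
the plain periodogram, for which the suite checks a Parseval-style
power/variance identity.

## Electrodermal activity

**Artifact epochs.** The signal is screened in 5-s epochs. The default
rule flags an epoch when the maximum absolute conductance slope exceeds
2.5 µS/s or the wrist-acceleration magnitude variance exceeds 0.01 g².
The slope threshold sits well above what a sudomotor response can produce
(a unit-peak Bateman kernel bounds the physiological slope at ≈2.4 µS/s
per µS of response amplitude, and real responses here are well under
1 µS) while step-like electrode artifacts at 4 Hz produce several µS/s.
A trainable sklearn-style classifier over the same epoch features
(slope, range, ACC variance, temperature slope) can be substituted for
the rule. Flagged epochs are excised from feature computation, not
interpolated.

**Decomposition.** Skin conductance is modelled as
`y = Bc + h ⊛ q + ε` with `h(t) = exp(−t/2.0) − exp(−t/0.75)` normalized
to unit peak (so driver amplitudes read in µS), `q ≥ 0` the sparse
sudomotor driver and `B` a cubic B-spline basis with 10-s knots for the
tonic level. The program

  min ‖y − h⊛q − Bc‖²/n + α·Σq/n + β·‖Δ²c‖²/k,  q ≥ 0

is smooth under the nonnegativity constraint (the L1 term is linear), so
it is solved with L-BFGS-B; the convolution operator is applied directly
(O(n·m) with a 16-s kernel support), making a 20-minute signal solve in
well under a second. Defaults α = 0.02, β = 0.01 were fixed once against
the closure behaviour of the generative model (clean recovery of isolated
0.3–0.6 µS responses, zero driver on constant input); α scales linearly
with signal amplitude, which the scale-equivariance test makes explicit.
The decomposition is performed on the full channel and artifact epochs
are masked afterwards at the feature stage; artifacts therefore appear as
driver bursts, but those live inside flagged epochs and never reach the
features.

**Features and peak counting.** Level statistics default to the tonic
component and peak statistics to the phasic component; the feature
table's printed labels conflate the two, so a `level_component="phasic"`
switch follows the printed text literally. Peaks are phasic local maxima
with prominence ≥ 0.05 µS ("strong" ≥ 0.30 µS) — thresholds are package
defaults, since the source states none — normalized per 100 s of
retained (non-artifact) time. Phasic peak counting has a physical
ceiling: when events arrive within the kernel rise time (~12% of Poisson
events at 10/min) the later response produces no local maximum at all,
so dense activity is undercounted by any peak picker. The deconvolved
driver separates such events; `count_scr_events` counts driver bursts
(height ≥ 0.05 µS, ≥ 0.5 s apart) and is the package's event-rate
estimator, recovering configured rates of 2 and 10 events/min within a
few percent where the phasic peak count saturates near 13/100 s.

## Acceleration, stillness and suggestion

Per-segment features are axis means, mean magnitude, and the spectral
energy of the mean-removed magnitude normalized so it equals the
time-domain sum of squares (Parseval). The stillness metric flags a
minute as still when at least 95% of its net-motion samples
(|‖a‖ − 1 g|) fall below 0.1 g; net motion is used so a motionless wrist
counts as still despite gravity (a raw-magnitude variant is selectable).
Minutes are non-overlapping and aligned to the session start. The
still-minute ratio is thresholded at 20%: the package default reads a
*high* ratio as a still, restricted context, because the opposite
(literal) reading makes a session almost all of whose minutes are
motionless "active"; the literal direction is available via
`literal_rule=True`. The suggestion map is a pure function: high + still
→ mobile relaxation, high + active → traditional relaxation, anything
else → none; an optional debounce window suppresses repeated suggestions.

## Learning stage

The learning stage follows scikit-learn estimator conventions —
`CBFSSelector` is a `SelectorMixin`, `StressLevelClassifier` a
`ClassifierMixin` wrapping an internal `Pipeline` — because selection,
reduction and classification are genuinely fit/predict shaped and this
lets them compose with sklearn model selection; the signal-processing
stages are deliberately plain functions, as they act on single channels
rather than sample matrices.

CBFS scores each feature by |Pearson correlation| with the class
indicator, taking the maximum over one-vs-rest indicators for three
classes (the two-class case reduces to the point-biserial correlation);
constant features score zero. Features are z-scored (training-fold
statistics) before kNN/SVM/LDA/MLP and before PCA; the random forest
(100 trees) consumes raw features. PCA keeps the smallest component
count reaching 0.95 cumulative explained variance. Grid search, when
enabled, is nested 3-fold inside the training folds over small
documented grids (MLP hidden sizes 16/64, kNN k ∈ 1–4, SVM C ∈
{0.1, 1, 10}). Cross-validation is 10-fold stratified with seeded
shuffling; reported accuracy is the pooled confusion-matrix trace ratio.
When a class has fewer members than folds the fold count is capped at
that class count, with a warning.

Two caveats are deliberate properties of the replicated workflow rather
than oversights. First, undersampling is applied once before
cross-validation (matching the toolkit-style workflow being reproduced),
which leaks marginal class-count information across folds; reducers and
scalers, by contrast, are strictly fold-local, and a unit test
demonstrates that fitting them with test rows included changes the
test-fold output. Second, cross-validation splits *segments*, not
subjects: overlapping segments from one session land in both train and
test folds, so session-specific fingerprints (e.g. a subject's baseline
RR) inflate accuracy relative to a subject-held-out design. The hard
simulator configuration disables between-subject offsets precisely so
this memorization channel does not mask its intended difficulty.

## Simulator

The generator reproduces the statistical structure the pipeline assumes,
not waveform-level physiology: the tachogram is mean + LF/HF sinusoids +
Gaussian noise (chosen over integral-pulse-frequency modulation because
band powers are then analytic); skin conductance is a drifting tonic
level plus Poisson events through the same Bateman kernel the
decomposition assumes; acceleration is gravity along a class-dependent
wrist orientation plus band-limited noise gated by minute-aligned active
bouts. Injected artifacts are multiplicative RR spikes (×1.5/×0.5) and
2-s conductance steps with coincident acceleration bursts, with exact
truth masks. Everything is deterministic under a fixed seed.

The *easy* configuration is the package's reference condition: 15
subjects × one 10-minute session per class, with high stress expressed
as shorter mean RR (650 vs 880 ms), LF-dominant spectral balance, a
higher SCR rate (10 vs 2/min) and more movement — directionally the
contrasts reported for real recordings. The *hard* configuration shrinks
all contrasts into the noise. Because the kernel matches the
decomposition's kernel, EDA closure tests are favourable by
construction; passing them shows the solver and plumbing are correct,
not that real electrodermal data (kernel mismatch, temperature drift,
electrode pops) would decompose as cleanly. Similarly, sinusoidal RR
modulation makes spectral recovery easier than real respiratory sinus
arrhythmia; the suite's tolerances are calibrated to these synthetic
conditions and transfer to real data only qualitatively.

## Problem sizes and numerical choices

The test suite and the acceptance script run everything at desk scale by
design: 100-series oracle checks, 300-s single-tone tachograms, 600-s
artifact-injection sessions, three 20-minute channels per SCR rate, and
the 45-session reference cohort (~390 merged segments). Degenerate
inputs are defined explicitly: empty channels and single-class tables
raise; a constant tachogram yields zero variability and zero band power;
a fully artifactual segment raises rather than emitting NaNs; spline
overshoot into non-positive intervals is replaced by the clean median.
Timestamps are epoch seconds, intervals milliseconds, and every interval
convention is half-open `[t0, t1)`.
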