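# Methods

## Scope

`freezecalc` re-implements, as a tested pipeline, the analysis of fearful
freezing behavior and thalamo-hippocampal (nucleus reuniens → CA1) axonal
calcium signals recorded in head-fixed mice navigating virtual-reality
contexts: freeze-epoch detection and behavioral feature engineering,
two-channel trace denoising and ROI combination, freeze-aligned activity
quantification, and a gradient-boosted-trees encoding model.  Because the
animal recordings are not bundled, every stage is exercised on a synthetic
generator that emulates the recordings with known ground truth; all
quantitative claims made by the test suite and the acceptance script are
about recovery of that ground truth, plus arithmetic identities on the
study's printed group statistics.

## Behavioral model and epoch detection

A session is a 322 s recording at 15.49 Hz of a mouse running a 200 cm
virtual track.  Completing a traversal triggers a 1.5 s teleport pause
(flagged per frame) before the next lap starts at 0 cm.

Epoch rules, applied to the signed velocity trace:

- **freeze** — maximal run of |v| < 0.001 cm/s lasting ≥ 12 consecutive
  frames (~0.75 s);
- **discarded** — sub-threshold runs shorter than 12 frames (neither
  freezing nor running), and isolated single frames of supra-threshold
  velocity;
- **run** — maximal run of v ≥ 0.001 cm/s sustained ≥ 2 frames;
- **backtrack** — the mirrored rule on v ≤ −0.001 cm/s (2-frame minimum),
  detected independently of running;
- **teleport** — flagged frames, excluded from all behavioral states.

Frames use 0-based half-open intervals.  The five kinds partition every
session exactly; an exhaustive frame-scan oracle enforces equality on
random sessions in the tests.  `%time freezing` divides freeze frames by
all non-teleport frames (freeze + run + backtrack + discarded) — the
teleport pause is dropped, extending the convention used for traversal
timing.  The discrimination index is DI = (s − c)/(s + c) on the two
contexts' freezing percentages, computed per mouse and then averaged
(computing the DI of group-mean percentages is the flagged alternative).

Per-frame predictors follow the feature list of the encoding model: epoch
ordinal ("freeze"), binary state indicators, sawtooth `elapsed`/`remaining`
counters in frames (elapsed + remaining = length − 1; progress =
elapsed/(length − 1), 0 at the first and 1 at the last frame of each
epoch), the combined freeze/run "interval" sawtooths that reset at every
state switch, velocity offsets at ±8 and ±15 frames (~0.5 s and ~1 s;
boundary frames are filled with the mean of the 15 edge frames, our
reading of "extrapolated from the prior 15 frames"), acceleration (first
difference × frame rate), 1 cm location bins, and the cleaned pupil
area/x/y.  Pupil cleaning removes frames whose blinking area falls below
mean − 2 SD, interpolates linearly, resamples to the imaging clock, and
smooths with a Savitzky–Golay filter (window 15 frames, order 3; the
source analysis states neither, these are conventional smoothing
parameters at this frame rate).

## Synthetic-data generator

The generator defines the study conditions the tests run under; its
defaults are fixed once and are not tuned against test outcomes.

**Behavior.** A two-state semi-Markov process: running bouts end with a
constant freeze hazard (per-second rate), freeze lengths are gamma
distributed (shape 2) and floored at the 12-frame detectability limit, and
the velocity during freezes is clamped to exactly 0 so ground-truth freeze
frames coincide with sub-threshold frames by construction.  Running
velocity is Gaussian (default mean 20 cm/s, SD 4, floored at 1 cm/s —
comfortably above the 4-traversals/minute inclusion criterion).  Shocks,
when enabled, arrive 20–26 s apart and trigger a 2 s sprint at 3× the mean
speed (the sprint magnitude is unconstrained by the source text, which
shows only its shape).  A shock scheduled during a teleport pause is
delivered at the first post-pause frame.

Cohort conditions (freeze occupancy of non-teleport time, mean epoch
length) are anchored to the printed day-1 statistics — shocked context
37% / 5.9 s, control 13% / 4.6 s on retrieval day 1, ~5% / 2 s pre-shock —
and decay toward baseline over the two extinction days (27%/5 s, 16%/3.5 s
shocked; 9%/4 s, 7%/3 s control).  The hazard for a target occupancy f and
mean length L is f/((1 − f)·L).  The pathway-silencing knob multiplies
freeze-epoch lengths (default 2.7, from 16.2/5.9 and 11.8/4.6) and raises
day-1 occupancy to 60%/35%.

**Calcium.** The latent transient rate is a low spontaneous baseline
(0.05 events/s) everywhere, plus, inside freeze epochs,
`tuning_amp × bow(progress)` where the bow profile (0.2, 1, 1, 1, 0.6 at
progress 0.1 … 0.9, linearly interpolated) encodes the rapid ramp, plateau
and pre-transition fall.  `tuning_amp` is 0 pre-shock and 0.8 events/s
post-shock.  Transients are Bernoulli events with jittered unit amplitude,
convolved with a single-exponential indicator kernel (τ = 1 s,
GCaMP6s-like; the kernel form is a modeling choice, not a measured fact).
One axon is split across 3 correlated ROI segments (per-segment gain
0.8–1.2); 2 further ROIs carry no signal.  A shared low-pass motion
artifact (Gaussian-filtered noise, σ = 0.5 s, amplitude 0.05) enters the
green and red channels of **every** ROI, which makes the red channel a
valid artifact regressor by construction.  The red channel is otherwise
constant at 1; per-channel Gaussian noise SD is 0.02.

**Pupil.** Slowly varying area/x/y (Gaussian-filtered noise, σ = 2 s);
blink events (0.05/s, 2–4 frames) collapse the blink-area trace far below
the mean − 2 SD threshold and artifactually depress pupil area.

**What the generator does not emulate** — and hence what passing tests do
not show about real recordings: imaging pixels, motion registration and
z-drift, neuropil contamination, reward-phase behavior, slow drift in
indicator brightness, non-Poisson burst statistics, and any coupling of
pupil state to axon activity.  Recovery results demonstrate that the
pipeline measures what it claims to measure when its assumptions hold, not
that the biological effect sizes are reproduced.

## Trace processing

Per ROI, both channels are Savitzky–Golay smoothed (window 7, order 3) and
the red channel is projected out of the green in variance space:
corrected = demeaned(G) − [Cov(G,R)/Cov(R,R)]·demeaned(R), using
population covariances.  The output has exactly zero covariance with the
red channel (property-tested to 1e-10 relative tolerance).

Same-axon ROI segments are identified by correlating each corrected ROI
against the mean of the others and comparing with a null built from 1,000
circularly time-shifted copies (uniform shifts ≥ 2 s).  An ROI passes when
it exceeds the null's 99th percentile **and** r² > 0.2 (the two criteria
are applied conjunctively; whether the original analysis applied them
conjunctively or sequentially is not recoverable, so both are enforced and
the r² floor is a parameter).  Passing ROIs are combined by PCA, taking
the first component with its sign fixed to correlate positively with the
across-ROI mean and its scale matched to that mean; remaining ROIs are
discarded.  If nothing passes, the single best-correlated ROI is kept so a
session always yields a trace.

ΔF/F uses a rolling 8th-percentile baseline over a 30 s window (the source
says only "baseline corrected"; window and percentile are configurable),
and each day's trace is rescaled by the 99th percentile of its ΔF/F so
near-maximum activity is 1 (we read "99th percentile of max activity" as a
percentile of ΔF/F, not raw fluorescence).  Peaks are scipy
`find_peaks` with height ≥ 0.1 ΔF/F, prominence ≥ 0.1, and minimum
separation ceil(0.5 s × 15.49 Hz) = 8 frames; a session passes activity QC
with ≥ 2 qualifying peaks.  An independent brute-force peak scan (with
plateau-midpoint and rightmost-tie handling) checks the detector
exhaustively in the tests.

## Epoch-aligned activity

Peaks are assigned to epochs by apex frame.  Three summaries:

1. **State peak means** — per-epoch mean normalized peak ΔF/F for freeze
   and run epochs; epochs without peaks are excluded from the grand state
   means (they carry NaN in the per-epoch table).
2. **Length-binned transition alignment** — freeze epochs grouped into 1 s
   total-length bins from 1–2 s to 6–7 s (epochs > 7 s dropped), each
   aligned at its freeze→run transition with the full epoch on the left
   and an equal-length run window on the right, NaN-padded; per-bin mean
   and 95% CI (normal approximation) per aligned frame.
3. **Progress profile** — each freeze epoch split into 5 equal-duration
   bins; per-bin mean normalized peak ΔF/F with empty bins counting as
   zero (so the profile reflects amplitude *and* occurrence — the
   opposite convention from summary 1, both documented because the source
   is silent on empty bins).

## Encoding model

XGBoost regression (`gamma=1, learning_rate=0.01, n_estimators=1000,
base_score=1, early_stopping_rounds=5`, seed 42).  Frames are grouped into
laps by teleport events; laps are partitioned 80/20 at random per draw and
no test-lap frame enters training (asserted per run).  Early stopping is
evaluated against the held-out laps, as the source describes — this mildly
inflates r²; a clean three-way split is available but not the default.
r² = 1 − RSS/TSS on test frames and may be negative.  `base_score = 1` on
a target normalized to peak ~1 means the model starts from near-maximum
activity and boosts downward; retained verbatim.  Chance level refits the
model after permuting the target trace across laps (lap lengths reconciled
by resizing).  Importances are summed split gain, reported as fractions
over six groups (freezing, velocities, running, interval, location,
pupil); acceleration is grouped with the velocities.

Because pre-shock axon activity is sparse, a single 80/20 draw can land
test laps containing almost no transients, collapsing the total sum of
squares and producing arbitrarily negative r².  The run regime is
therefore always repeated draws with the per-session **median** r² (100
draws in the full regime; 5 draws in the scaled-down acceptance runs).

## Problem sizes

Full study scale is 10 mice × 4 days × 2 contexts × 100 draws = 8,000
model runs.  The test suite and acceptance script run a scaled-down mirror
chosen as a desk-scale default: 4-mouse cohorts, 322 s sessions, 10–20
generator seeds, 5 encoding draws per session, and 300 shuffles in the ROI
null (1,000 is the analysis default).  Oracle-equivalence checks use 100
random sessions/traces of up to 2,000 frames.

## Numerical choices and degenerate inputs

Population (1/n) covariances throughout the orthogonalization; constant
red channel, constant combined trace, non-positive baseline, constant
r²-target, fewer than 5 laps, and empty sessions all raise typed errors
rather than propagating NaNs.  A freeze-epoch table with no freezes
returns count 0 and NaN mean.  Progress of a length-1 epoch is defined as
0 (cannot occur for freezes, which are ≥ 12 frames).  0.5 s at 15.49 Hz
rounds up to 8 frames.  PCA sign/scale conventions are as above; ties in
peak height are resolved toward the rightmost peak (matching the detector
contract).

## Known limitations

- Group-level inferential statistics (repeated-measures ANOVA, estimated
  marginal means, robust regression) are out of scope; only descriptive
  aggregation is implemented.
- The encoding model's early stopping on the test split biases r² upward
  for both tuned and untuned sessions; comparisons between conditions are
  unaffected but absolute r² values should not be read as unbiased.
- Synthetic effect sizes (tuning amplitude, noise levels) are package
  choices anchored to printed behavioral statistics, not fitted to the
  deposited recordings; absolute r² and peak-rate values are therefore not
  comparable to the study's real-data numbers.
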