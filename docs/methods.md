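# Methods

This note documents the modelling choices, defaults and known limitations
of the package. Everything quantitative stated here is computed by the
test suite or by `scripts/acceptance.py`.

## Synthetic sessions

`synthetic.simulate_sessions` draws, per session, two independent binary
Markov chains: a speed chain and an accuracy chain, each with
configurable self-transition probability (default 0.85, i.e. mean dwell
1/(1−0.85) ≈ 6.7 trials, matching the few-trial stretches typical of this
kind of task). The five metrics depend only on their own axis chain
(cross-talk available, off by default):

| metric    | emission                         | low state | high state | SD   |
|-----------|----------------------------------|-----------|------------|------|
| hit       | Bernoulli                        | 0.55      | 0.90       | —    |
| bias      | Bernoulli                        | 0.40      | 0.05       | —    |
| precision | truncated Gaussian on [0, 1]     | 0.68      | 0.72       | 0.10 |
| rt (s)    | truncated Gaussian (> 0.05)      | 1.8       | 1.0        | 0.40 |
| speed     | truncated Gaussian (> 1) units/s | 120       | 180        | 30   |

Defaults are package choices: hit rates bracket a realistic
two-alternative range; the continuous metrics are separated by two
within-state SDs; precision is deliberately only weakly coupled to the
accuracy chain, reproducing the empirically loose association of endpoint
precision with either performance axis (it consistently attains the
lowest silhouette in the metric clustering). Movement speed and duration
scales are set so typical path lengths (~500–700 VR units) sit well above
the 250-unit exclusion threshold.

Optional structure: a slow rhythm replaces the speed chain by a square
wave of period P with per-trial label flips (default flip probability
0.15) — a binary sequence with a controllable planted period for the
spectral analyses; per-metric quadratic drift over the session; a
human-like learning transient (exponentially decaying RT surcharge and
speed deficit over the first ~50 trials); difficulty levels drawn from a
discrete set in [0, 1] whose (centred) level shifts error probability and
RT when `difficulty_effect` > 0. Trial durations are log-normal around
`mean_trial_duration_s` (needed only for the seconds-domain spectrum).
Miss trials (a configurable fraction of non-correct outcomes) have no
endpoint, so their RT and precision are undefined and the trial is later
removed by the missing-value filter. Everything is reproducible from a
single integer seed.

`simulate_trajectory` produces 2-D paths (zero-mean lateral position
before a planted turn time, constant lateral drift toward the chosen side
after, additive Gaussian noise) as ground truth for the reaction-time
detector.

## Reaction-time detection

A sliding-window linear regression of lateral position on time (window
0.25 s of samples) with exponentially decaying weights (half-life = one
window; recent samples count more) yields a slope series. The baseline
slope noise is estimated robustly (1.4826 × MAD over the first 20% of the
trial) and a turn is declared when |slope| exceeds 3 robust SDs for at
least half a window (adjacent windows overlap, so noise excursions persist
about one window and a sustained criterion is required); the reported RT
back-tracks from the crossing to the last sample at baseline noise level.
On noiseless paths this recovers the turn time to within one sample; on
noisy paths (lateral noise 4 VR units, 200 trials) detected and true RTs
correlate at r ≈ 0.99 with a median absolute error of ~0.07 s. All
constants are exposed as arguments and validated by recovery, not by
matching any particular dataset.

## Preprocessing

Fixed order per session: missing-value/duration/path-length filter →
(humans only) learning cutoff → quadratic detrend of the *continuous*
metrics (precision, RT, speed; the binaries are left untouched) → 5-trial
centred rolling mean for all five metrics (shrinking windows at the edges
so the trial count is preserved for HMM alignment) → per-session,
per-metric standard scaling. Sessions are then concatenated per group.
The learning cutoff compares 20-trial rolling means of RT and speed with
the mean of the second half of the session and returns the first index
from which both remain within 1 second-half SD; window and tolerance are
package defaults (exposed), since no canonical values exist. Per-session
(rather than per-group) scaling is the default; a single flag switches.

## State inference

One Gaussian HMM per axis (full covariances) on the concatenated
sessions, with 50 pad trials of the constant +10 (standardised units)
between sessions; the model carries one extra state that must absorb ≥90%
of the pad trials and is discarded — the only reading that reconciles a
2-state model with a reliably-classified third padding state. Decoding is
per-trial posterior argmax by default (Viterbi available). States are
canonicalised semantically: *fast* = higher mean standardised movement
speed, *accurate* = higher mean hit rate; composite label = 2·speed +
accuracy, named distracted/deliberate/impulsive/efficient.

Numerical choices that matter:

* **Covariance floor.** Smoothed Bernoulli metrics are discrete (atoms at
  multiples of 1/w); an unconstrained Gaussian state can collapse onto an
  atom (e.g. the all-zero bias window) for an unbounded likelihood gain.
  hmmlearn does not enforce `min_covar` in the full-covariance M-step, so
  the fit uses a subclass that floors covariance eigenvalues at 0.05
  (standardised units²) each M-step. The floor can bend exact EM ascent
  at the boundary; the monotonicity diagnostic is therefore run on
  pad-free continuous data where it does not bind.
* **Initialisation.** kmeans means plus *per-cluster* covariances and a
  small mean jitter per restart. Initialising every state at the global
  data covariance (hmmlearn's default) lets EM merge separable clusters
  into one state. 10 restarts by default, best log-likelihood wins;
  restarts whose padding state fails to separate, or that place a second
  near-singular state on the pads, are rejected.
* EM: tol 1e−4 on the log-likelihood, max 500 iterations, seeds derived
  from one master seed.

A single 4-state HMM over all five metrics is available as a comparison
fit (same padding logic, no semantic canonicalisation).

### What smoothing does to trial-level recovery

The 5-trial centred mean maps a length-1 state run to a 0.2-amplitude
boxcar and a length-2 run to a 0.4 plateau; neither crosses the midpoint
between state means, so such runs are misdecoded by *any* decoder even
with noise-free emissions. Under geometric dwell at self-transition 0.85,
runs of length ≤ 2 are ~28% of runs, bounding per-axis trial agreement
with the planted chains near 94% at zero noise and ~87% at 2-SD
separations (errors concentrate within ±1 trial of true switches), hence
composite agreement near 0.77. This is a property of the pipeline, not a
defect of the estimator: the smoothing window trades single-trial
recovery for robustness to trial-level noise, and its footprint is
exactly the linear dwell-time inflation quantified by the
smoothing-window sweep (median decoded dwell grows ~linearly over
w ∈ {2, 5, 10, 20}, R² > 0.9). Parameter-recovery checks of the HMM
estimator itself (e.g. self-transition 0.9 recovered within ±0.05 at
T = 10,000) are run without smoothing on the continuous speed axis for
this reason.

## State dynamics

Runs never cross session boundaries and boundary trials are never
switches. Transition matrices are bigram MLEs within sessions, reported
with and without the diagonal (off-diagonal variant renormalised; rows of
unvisited states masked). The block-shuffle null permutes run *lengths*
within each label class per session, keeping the label order — permuting
whole blocks would merge same-label neighbours and change the run-length
multiset, which this scheme preserves exactly. Switch coupling uses
per-session circular shifts of magnitude > max_lag so that trivial
alignment is excluded while each sequence's autocorrelation is intact.
Empirical p-values use the (b+1)/(n+1) correction; two-sided p doubles
the smaller tail; BH-FDR is applied across cells/lags as appropriate.
Dunn's post-hoc test (rank z-tests with tie correction, Bonferroni) is
implemented in-package. Half-session splits put the odd middle trial in
the first half. Fingerprints are 4 states × 5 metrics means of the
standardised metrics per session; unvisited states are NaN-masked and
excluded pairwise.

## Superlet spectra

One trial = one sample at nominal rate 1000, so frequency is in cycles
per 1000 trials and period (trials) = 1000/f exactly; the analysed band
6.7–66.7 cycles/1000 trials spans periods 150 down to 15 trials (121-point
grid by default). Per frequency, a set of amplitude-normalised Morlet
wavelets with cycle counts base·{1..o} (base 3; order o growing linearly
from 1 at the lowest frequency to 5 at the highest; Gaussian envelope
σ = cycles/(5f), truncated at ±2.5σ) is convolved with the mean-centred,
mirror-padded session; the power is the squared geometric mean of the
magnitude responses. These constants are package choices validated by
planted-period recovery (a planted 55-trial rhythm is recovered at 54.95
trials, a 75-trial rhythm at 75.76 — the grid discretisation). Sessions
shorter than the longest wavelet support (~225 trials at the default
band) are skipped with a warning.

The shuffle null permutes whole trials within sessions *before*
detrending/smoothing/scaling, then re-runs the HMM fit, decoding and
transform per surrogate — so the null carries the full pipeline's
footprint, including any rhythm the smoothing or model could manufacture.
At the default 1000 surrogates this is the most expensive computation in
the package; a reduced-repetition mode is supported and warns below 100
surrogates. Session-level peak periods are extracted in the 40–80-trial
band (ties toward the longer period) and compared between groups by
label permutation with subsampling to matched group sizes (Bonferroni
across pairs). The seconds-domain variant repeats each trial's label
round(duration) times.

## Difficulty around transitions

The difficulty series is averaged in a ±10-trial window aligned to
speed-state transitions of a given direction (transitions without a full
window are excluded). The default null redraws the same number of
transition positions uniformly within each session, preserving the
difficulty series' autocorrelation; a difficulty-shuffle null is available
behind a flag since either control is defensible. Offsets outside the
2.5–97.5 percentile band are flagged. Note that with planted
difficulty-triggered transitions the positions-null mean *includes* the
spiked trials, so off-centre offsets can flag low — only the
transition-trial offset flags high.

## Orchestration

`run_pipeline` executes simulate → preprocess → cluster → fit → dynamics →
spectrum → difficulty; each stochastic stage draws its seed from a fixed
substream of one master seed, so changing one stage's repetition count
never shifts another stage's randomness, and a fixed master seed gives
byte-identical outputs. A manifest (version, seeds, parameters) is written
alongside the outputs. The CLI (`attnstates <stage|all>`) is a thin layer
over this function.

## Problem sizes used in the shipped checks

Recovery and calibration runs are sized for a single CPU: composite
recovery at 20 sessions × 300 trials; parameter recovery at T = 10,000;
calibration at 200 Monte-Carlo repetitions with 99 permutations each (99
makes the discrete p-grid include 0.05 exactly); planted-period targets at
10 sessions × 500 trials; the pipeline-level shuffle null at 25–40
surrogates in tests (with the documented instability warning).

## What the synthetic data does and does not show

The generator reproduces the *structure* the analyses assume — two latent
binary chains, state-conditional emissions, slow drift, a planted rhythm,
difficulty effects — so passing tests demonstrate that the pipeline
recovers planted structure and that its null procedures are calibrated.
It does not emulate session-to-session heterogeneity, reward/satiety
dynamics, within-trial kinematics beyond a single turn, pupil-linked
arousal, or realistic inter-metric noise correlations; conclusions about
real behaviour still require real sessions. Emission parameters are
package choices throughout, since no reference parameter set exists.
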