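# Methods

This note documents the models and procedures implemented in `neuromux`, the
parameter choices that matter, and the limits of what the synthetic data can
show.

## Task structure and data model

A session presents 8 stimuli in a delayed paired-association design: four
complex multicolor images and four uniform grays (43.1, 54.9, 86.3, 98 %
white; the category boundary at 70.6 % white makes 43.1/98 the
high-contrast and 54.9/86.3 the low-contrast members). Each stimulus carries
a *value* level — reward probability 0.9/0.3 for complex stimuli, contrast
high/low for grays (rewarded at 0.5) — and an associated left/right choice.
Trials are 1 s sample + 3 s delay; spike times are stored per trial in
seconds relative to sample onset over [-0.5, +4.25] s. All neural analyses
use correct trials only by default (error trials are generated and stored,
and can be included by flag), and the two stimulus classes are always
analyzed separately.

## Sliding-window ANOVA and classification

Spike counts are taken in half-open windows [start, start + 0.25 s) with
starts -0.5, -0.4, ..., 3.9 s (45 windows). This grid gives each 1 s phase
(sample [0,1), delay1 [1,2), delay2 [2,3), delay3 [3,4)) exactly 10 window
starts; the last windows of a phase extend up to 150 ms past its end, which
is the unavoidable cost of having 10 bins per phase at 100 ms steps. Phase
membership is by window start, and a two-window run straddling a phase
boundary counts for neither phase.

Each window's counts enter a crossed 2x2 ANOVA (value x choice) with
interaction. Because correct-trials-only filtering makes cells unbalanced,
sums of squares are Type III with sum-to-zero contrasts — for the 2x2
design these are the classical unweighted-means contrast sums of squares,

    SS(contrast) = L^2 / (sum_c 1/n_c / 4),

with L the half-difference of unweighted cell means, which reduces to the
Type I decomposition on balanced data (both equivalences are verified in the
test suite against an explicit mean-based oracle and against an independent
OLS/Type III fit). Partial eta squared is SS_effect / (SS_effect +
SS_error). A window with an empty design cell is marked invalid (eta = 0)
rather than raising.

Classification per phase and category uses the threshold eta_p^2 >= 0.03
sustained over two consecutive windows (both inclusive comparisons and the
run length are configurable). The *stimulus* category — an idiosyncratic
response to one stimulus — requires choice, value and interaction to pass in
the same two consecutive windows, since a single elevated cell of the 2x2
design raises all three effects simultaneously. Categories are deliberately
non-exclusive at this stage.

Per-neuron mean effects per phase average eta_p^2 over the phase's 10
windows. By default, windows outside qualifying two-consecutive runs
contribute zero ("thresholded" mode): raw averaging would put the null
expectation of the mean near eta ~ 1/df, visibly above the near-zero
population means this statistic is meant to report; a "raw" mode is
available. Runs are detected on the whole track before phase averaging, so a
run crossing a phase boundary still contributes its windows to their
respective phases.

## Chance levels and enrichment

Chance counts re-run the identical pipeline on label-shuffled data: per
neuron and permutation, the (value, choice) pair is permuted jointly across
trials — preserving the stimulus-to-condition yoking of the pairs and all
cell sizes — and one shuffle applies to all 45 windows. 200 permutations per
neuron, drawn independently per neuron from one seeded generator. Shuffled
data essentially never show the strict three-effect stimulus signature, so
the stimulus category uses a relaxed 2-of-3 rule in the permutation arm
only. Mean counts over permutations are rounded up (ceil) to integers before
entering the 2x2 Fisher table [[observed, n - observed], [chance, n -
chance]]; the test is one-sided (enrichment), and 20 tests per stimulus
class (4 phases x 5 columns, counting the any-flag "cell total" column) are
Bonferroni-controlled at 0.05/20 = 0.0025.

## Multiplexing categories and class contrasts

The mutually exclusive labels are derived from the phase flags alone, with
phase order sample < delay1 < delay2 < delay3:

- **early choice** — choice flag in the sample phase, no stimulus-type flag
  (stimulus, value or interaction) in any phase;
- **late choice** — choice flag first appearing in a delay phase, no
  stimulus-type flag anywhere;
- **stimulus – no choice** — stimulus-type activity somewhere, no choice
  flag anywhere;
- **stimulus – choice** — stimulus-type activity in an earlier phase and a
  choice flag in a strictly later phase (same-phase co-occurrence is not a
  switch);
- **uncategorized** otherwise.

Label counts between classes are compared with Pearson chi-square, df = 1,
without continuity correction (the uncorrected statistic reproduces the
reference values 9.58, 5.33, 6.41 from counts 6 vs 21, 13 vs 26, 16 vs 5 of
104). Preference among stimulus-coding neurons for high- vs low-value
stimuli uses a goodness-of-fit chi-square against an even split.

Trace decay: the population-mean choice eta_p^2 is computed per window
position and the 10 positions of delay1 are paired with those of delay3
(paired t, df = 9, positive t = decay). The pairing is across window
positions, not neurons — the only reading consistent with df = 9 at 10
windows per phase.

## Spike-density functions

The smoothing kernel is the density of N(0, sigma^2) + Exp(tau) with sigma =
tau = 100 ms and the exponential tail toward positive time (standard causal
orientation for spike smoothing). It is built by discrete convolution of the
two densities, truncated at +/-(5 sigma + 5 tau), and renormalized to unit
mass, so one spike contributes one unit of integrated rate. No edge
correction is applied; the recommended grid extends 0.25 s beyond the
analysis interval so the interval of interest stays interior.

## Gabor complexity

The bank holds 68 filters: orientations {0, 45, 90, 135} degrees by sizes
s = 1..17 with sigma(s) = 0.0036 s^2 + 0.35 s + 0.18 px and carrier
wavelength lambda = sigma / 0.8; the envelope aspect ratio gamma defaults to
1 (circular) as no value is prescribed. Filters are sampled on square grids
of half-width ceil(5 sigma) px (> 99.999 % of envelope mass). Images are
converted to luminance with Rec. 601 weights, reflect-padded, and convolved
at 'same' extent; the feature is the mean absolute response, and the
complexity index is the median of the 68 features.

Normalization is configurable because at lambda = sigma / 0.8 the Gabor
integral is numerically ~0 (ratio to the absolute integral ~5e-6 for
s >= 4), making a reciprocal-of-integral constant explosive. The default
`unit_sum` mode divides by the positive filter mass, enforcing the natural
contract that filtering a [0, 1] image can never exceed 1; `reciprocal`
implements the literal reciprocal-integral constant with its Heaviside
correction and raises with guidance when the integral underflows;
`zero_mean` subtracts the filter mean first, making constant images map to
exactly zero features. The filter's pixel units are nominal: no physical
image resolution is prescribed, so complexity comparisons are valid within a
fixed image size only.

## Synthetic sessions

Spiking is an inhomogeneous Poisson process with piecewise-constant rate:
baseline plus additive condition gains per the neuron's coding profile. This
is the simplest generative model with the factorial mean structure the ANOVA
assumes; refractoriness, bursting, latency jitter, and rate drift are
deliberately absent and irrelevant to count-based ANOVA at 250 ms windows.
Profiles: *early choice* (choice gain from sample onset), *late choice*
(from delay onset), *value coder* (gain for one value level, sample +
delay1), *stimulus – no choice* (gain on the two diagonal value-by-choice
cells during the sample — a pure interaction pattern with no choice main
effect; a strict single-stimulus response cannot satisfy "no choice flag"
since one elevated cell raises all three effects), and *stimulus – choice*
(single-stimulus gain during the sample handing over to a choice gain at the
switch time, default 1.0 s). Choice-gain decay across the delay is
exponential in the delay-phase start times: gain x exp(-(t_phase - 1)/tau).

Defaults are fixed once as the package's study conditions: 8 stimuli x 80
trials, error rates 8.3 % (complex) and 16.8 % (simple) matching the
delayed-condition performance the task produces, baseline rates uniform in
5–20 spikes/s (conventional forebrain single-unit range), effect gain 8
spikes/s, early-choice decay tau 1.5 s. The trial count follows from the
analysis's own calibration anchor: with eta threshold 0.03 equivalent to
F(1, df) at p ~ 0.01 — the reported property of above-threshold windows —
df_error must be >= ~215, i.e. >= ~55 trials per stimulus; 80 puts the
threshold at p ~ 0.003 per window, where chance classifications are rare.
At materially smaller sessions (e.g. 30 trials/stimulus) the same absolute
threshold admits a large false-flag rate and multiplex labels of genuinely
coding neurons are frequently contaminated; this is a property of the
fixed-threshold method, not of the implementation.

What passing tests show — and do not show. Parameter recovery (>= 90 %
correct multiplex labels at the defaults) and permutation-null calibration
demonstrate internal consistency of the pipeline under its own generative
assumptions. They do not certify performance on real recordings, where
firing-rate nonstationarity, non-Poisson variability, and session-to-session
heterogeneity can move both the false-flag rate and the power of the
two-window criterion. The residual labeling errors at the defaults are
informative: neurons with choice onset exactly at delay onset occasionally
earn a sample-phase flag because the windows starting at 0.8/0.9 s extend
into the delay — boundary bleed inherent to start-time phase membership.

## Numerical choices and degenerate inputs

- Window starts are rounded to 9 decimals; phase membership comparisons use
  a 1e-9 tolerance.
- An ANOVA window with any empty cell, or fewer than 5 trials, is invalid:
  eta = 0, p = 1, flagged, never an exception.
- SS_error is clipped at 0 against roundoff; 0/0 eta is defined as 0; with
  SS_error = 0 exactly, eta is 1 (p = 0) for positive effect SS and 0
  otherwise.
- Ceil of the mean chance count maps 1.2 -> 2 and 3.0 -> 3 (plain ceiling).
- Cohen's d raises on zero variance rather than returning infinity.
- The trial-label permutation intentionally bypasses the
  stimulus-to-condition consistency validation that applies to real trial
  tables.

## Known limitations

- The linear mixed models used for behavioral and class comparisons in the
  original workflow are out of scope; the package emits the tidy per-session
  and per-neuron tables such fits consume, plus Cohen's d for paired
  contrasts.
- The outcome (reward) phase is not analyzed.
- Complex stimulus images are procedural textures, not photographs; they
  reproduce the statistical property that matters here (multi-orientation,
  multi-scale spatial content), not the appearance of any particular
  stimulus set.
- No NWB/continuous-voltage ingestion or spike sorting; inputs are
  plain-text trial tables and spike-time lists.
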