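# Methods

## Turn coding

Raw Y-maze data are arm-entry events `(time_s, subject_id, zone)` with zones
drawn from three arm labels plus a centre label. Coding proceeds in three
deterministic passes: (1) entries dwelt in for less than `debounce_s` are
dropped (default 0 — every entry counts; the final entry's dwell is
open-ended and always kept); (2) centre entries are set aside, counted for
QC; (3) runs of the same arm are collapsed, each collapsed run counting as a
same-arm re-entry. Every remaining transition between distinct arms emits
one token, stamped with the entry time into the new arm: with the arms in
clockwise order (viewed from above), moving to the clockwise neighbour is
`R` and to the counter-clockwise neighbour `L`. The assignment of physical
rotation to "left"/"right" depends on the rig's camera and labelling
orientation, so the geometry carries a `reflect` flag that mirrors the
convention; coding is invariant under rotation of the arm labels and
complements under reflection (property-tested). A same-arm re-entry
(arm → centre → same arm) completes no left/right choice and emits no
token; it is surfaced in QC counters rather than silently discarded.

Time bins are half-open, `[k·600 s, (k+1)·600 s)` by default (six 10-min
bins per 1-h session); a turn stamped exactly at the session end falls into
the last bin, and turns beyond the session length are a data error.

## Tetragram metrics

Tetragrams are the 16 words of length 4 over {l, r}, counted in a sliding
window of stride 1 over the **whole-session** token stream (not restarted
per bin): a stream of n turns yields max(0, n − 3) windows. Relative
frequencies use the window count as denominator, so the 16 frequencies sum
to 1; with fewer than 4 turns the profile is degenerate and reported as
missing, not zero. Alternation score = (lrlr + rlrl)/windows; repetition
score = (llll + rrrr)/windows. When a per-bin breakdown is requested, a
window is assigned to the bin of its fourth turn — the pattern exists only
once its final choice completes — so windows straddling a bin edge are
neither dropped nor double-counted.

Bias percentage is `100 · count(side)/total`; left and right are exactly
complementary. Classification applies a strict threshold (default > 60 %)
to the whole-session bias — not to the mean of per-bin biases, which is a
different (and noisier) statistic. Per-bin consistency reports the mean and
CV (100 · sample SD / mean, SD with n − 1) of the per-bin bias percentages
over bins containing at least one turn; empty bins are excluded and
counted, and fewer than two usable bins yields missing consistency.
Subjects with fewer than `min_turns_for_inclusion` turns (default 20) are
scored but flagged excluded as non-engaged; the cohort class summary covers
included subjects only.

## The generative turn model

The synthetic generator draws tokens from a two-state first-order Markov
chain, the minimal model spanning the two axes the analysis measures:
marginal side bias and the alternation–perseveration continuum. With
`a = P(R | L)` and `b = P(R | R)`, the stationary law is
`π_R = a/(a + 1 − b)` and the second eigenvalue of the transition matrix is
`λ = b − a`. Setting `a = b` gives an i.i.d. Bernoulli stream; `a > b`
favours alternation, `a < b` perseveration. Turn times are a homogeneous
Poisson process (exponential inter-turn gaps, `turn_rate_per_min`)
truncated at the session length, the simplest timing model compatible with
per-bin turn-count analysis. Each simulated fish is also encoded as an
arm-entry path (with interleaved centre passages) so simulations exercise
the full file → event → token pipeline; the encoder and coder are exact
inverses (tested at 1,000+ transitions).

Expected tetragram frequencies have the closed form
`E[f_w] = π(w₁) · Π P(w_{k+1} | w_k)`, which sums to 1 over the 16 words;
an independent test oracle recomputes them from the eigendecomposition of
the chain lifted to 3-token histories (8 states). For the reducible chain
(a = 0, b = 1) the stationary law is not unique and the initial law is used
instead, matching the long-run window frequencies of a chain frozen in its
initial state.

**Sampling variance of overlapping windows.** Overlapping tetragram counts
are not binomial: a self-overlapping word (llll, rrrr — and, weakly,
lrlr/rlrl) recurs in bursts, inflating its count SD to ≈ 1.6× the binomial
value, while non-self-overlapping words are deflated (≈ 0.8×). The package
computes the exact variance by summing (i) the lag-1..3 overlap
covariances from the merged-word joint probabilities and (ii) the lag ≥ 4
geometric tail through `λ`:
`cov_d = p·q·λ^{d−3}·(δ(w₄,w₁) − π(w₁))`, with `q` the word's internal
transition product. This closed form is Monte-Carlo-verified in the test
suite (300 replicate streams) and is the standard error used whenever
simulated frequencies are compared with the oracle at 3 SE — calibrated for
the self-overlapping words and *tighter* than binomial for the rest.

### Default cohort

The default simulated cohort mirrors the reported laterality profile of a
103-fish zebrafish cohort: 28 left-, 28 right-, 47 non-biased. Class
parameters are fixed, documented constants chosen to reproduce the
qualitative class contrasts (biased fish repeat more, alternate less;
right-biased fish turn less often), not any particular cohort's means:

| class        | a    | b    | π_R  | turns/min |
|--------------|------|------|------|-----------|
| non_biased   | 0.65 | 0.35 | 0.50 | 6.0       |
| left_biased  | 0.28 | 0.28 | 0.28 | 6.0       |
| right_biased | 0.72 | 0.72 | 0.72 | 4.5       |

Individual fish jitter around their class: additive Gaussian SD 0.02 on a
and b (clipped to [0.01, 0.99]) and log-normal SD 0.10 on the rate. The
jitter is deliberately small relative to the 12-point margin between the
biased marginals (72 %/28 %) and the 60 % threshold, so class identity is
preserved: at ~270–360 turns per session the binomial SD of the observed
bias is ~2.7 points and misclassification is rare (<1 %), which is what the
≥ 95 % end-to-end recovery check exercises. Conditional-frequency
estimates of (a, b) from a 2,000-turn stream have SE ≤ 0.019, so the 0.05
recovery band corresponds to ≥ 2.6 SE (≈ 99 % of seeds).

## Occupancy scoring

Trajectories are point samples; between samples the fish is assumed to hold
its last position (zero-order hold), so every endpoint is a time-weighted
sum of holding intervals. Holding intervals longer than a gap tolerance
(default 1 s) are truncated, the score is reported over covered time, and a
warning is raised — gaps are a tracking failure the user should see.

**Avoidance preference.** The arena is split at the midline (the "vicinity
of CS+" is the CS+ half; the split point is configurable since no vicinity
radius is standard). The CS+ side follows the schedule at every instant:
during habituation *and* baseline the patterns swap sides every 5 min — so
baseline preference is side-counterbalanced — and during the probe the
sides swap once at 30 s. Conditioning trials show a single full-field
pattern, so sidedness is undefined and those samples are never scored.
Preference is the fraction of covered phase time on the CS+ side; CS+ and
CS− fractions are exactly complementary. Absolute seconds are emitted
alongside.

**Novel tank.** The height is divided into three equal slabs for
bottom/middle/top occupancy (front view); distance is the summed Euclidean
step length in the top view; immobility is the total duration of runs in
which top-view speed stays below 0.5 cm/s for at least 2 s (a run reaching
the final sample extends through that sample's holding interval);
thigmotaxis is time within 2.4 cm (20 % of tank width) of any wall in top
view. The speed and margin thresholds are explicit configuration — field
conventions vary and the endpoints are threshold-sensitive, so they are
never hard-coded. Out-of-bounds samples are clipped to the tank box rather
than dropped, conserving occupancy time; the clip count is surfaced for QC.

**Trajectory generators.** The tank simulator is a reflected random walk;
the vertical coordinate optionally mean-reverts toward a preferred height
(`anxiety_depth_bias` ∈ [−1, 1]; 0 disables the pull entirely so the
stationary depth law is uniform and thirds occupancy is 1/3 each — the
symmetry the null tests rely on; the pull strength at full bias confines
the depth to roughly ±2 cm), and a wall-attraction drift produces
thigmotaxis. The conditioning simulator is a 1-D reflected walk, driftless
until conditioning onset and drifting away from the scheduled CS+ side at
`avoidance_strength` cm/s thereafter. All drifts and steps scale with the
speed parameter, so speed 0 freezes the fish. Every generator is
reproducible: same seed, identical output.

## Group statistics

Group summaries are mean ± SEM (sample SD/√n; SEM missing for singleton
classes). Between-class contrasts use two-sided label-shuffle permutation
tests on the difference of group means with the add-one estimator
`p = (1 + #{|null| ≥ |obs|})/(B + 1)`, which is valid (conservative) under
exchangeability and can never return 0. This deliberately replaces
model-based inference (Poisson GLMMs, repeated-measures ANOVA with post
hocs): those are off-the-shelf fits orthogonal to this package's
contribution, while permutation contrasts are assumption-light and exactly
calibrated under the simulator's null — the suite verifies a type-I error
of 0.05 ± 0.02 over 1,000 no-effect repeats. Multiple-testing correction
(Benjamini–Hochberg) is available but off by default; the choice is left
explicit to the user.

## What the simulations do and do not show

The generator reproduces the statistical *structure* the analysis assumes —
first-order choice dependence, Poisson turn timing, drift/mean-reversion
occupancy — with known parameters, so passing tests demonstrate that the
pipeline recovers truth when the data match its assumptions. Real fish
violate them in known ways: choice sequences can carry higher-order and
non-stationary structure (fatigue, habituation within the hour), turn rates
are not constant, swimming has momentum and burst-glide dynamics rather
than white-noise steps, and tracker noise is not modelled at all beyond
debounce/clipping hooks. Recovery rates measured here are therefore upper
bounds on real-data performance, not estimates of it; group contrasts in
real cohorts additionally depend on effect sizes no simulation can supply.

## Numerical and edge-case conventions

- Undefined quantities (bias of zero turns, consistency with < 2 usable
  bins, tetragram frequencies with < 4 turns) are NaN/missing, never 0.
- Exactly-at-threshold bias is non-biased (strict inequality).
- A position exactly on the arena midline counts as the right side; a depth
  exactly on a third boundary belongs to the slab above it (half-open
  slabs).
- Result CSVs serialize floats at shortest round-tripping precision;
  readers parse with exact round-trip mode, so write → read → write is
  byte-identical.
- Problem sizes in the verification suite (10,000-turn oracle streams,
  200-seed recovery, 200-replicate avoidance runs, 1,000-repeat
  calibration) are sized so each check's Monte-Carlo error is small against
  its tolerance while the whole suite stays fast enough to run on every
  change.
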