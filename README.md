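# fmpmaze

Analysis pipeline for **free-movement-pattern (FMP) Y-maze** laterality in
zebrafish, together with Pavlovian avoidance preference scoring and
novel-tank anxiety endpoints — plus a synthetic-behavior generator with
closed-form oracles so every stage can be verified without animal data.

## Who this is for

Behavioral neuroscientists and computational ethologists who record
continuous exploration in a three-arm maze (each passage through the fork is
a binary left/right choice), conditioned place-avoidance trajectories, or
novel-tank diving trajectories, and want a tested, scriptable alternative to
ad-hoc spreadsheet scoring.

## What it computes

**Y-maze laterality.** From an arm-entry event log, each transition between
distinct arms is coded `L` or `R` (clockwise neighbour = `R` by convention;
a `reflect` flag mirrors it). The pipeline then reports, per fish:

- the 16 overlapping **tetragrams** (sliding windows of 4 consecutive
  choices over {l, r}): counts and relative frequencies, with
  *alternations* = lrlr + rlrl and *repetitions* = llll + rrrr as
  proportions of the (n − 3) windows;
- the **bias percentage**, `100 · (turns to one side) / (total turns)`,
  over the whole session and per 10-min bin;
- per-bin **consistency**: mean and coefficient of variation
  (CV = 100 · SD/mean, sample SD) of the per-bin bias percentages;
- a strict three-way **class label**: `right_biased` if overall R-bias
  > 60 %, `left_biased` if L-bias > 60 %, else `non_biased` (threshold
  configurable);
- cohort-level class counts and percentages, mean ± SEM group summaries,
  and permutation contrasts between classes.

**Avoidance conditioning.** From a lane trajectory and the phase schedule
(30-min habituation with 5-min side alternation, 10-min baseline, 9 trials
of 1.5 s CS+ → shock → 8.5 s ITI, 1-min probe with a side switch at 30 s),
it scores the time-weighted fraction of baseline and probe time spent on
the CS+ half of the arena and their difference (`delta_pref`; avoidance
learning shows as probe < baseline).

**Novel tank.** From synchronized front/top trajectories of a 5-min trial
in a 30 × 15 × 12 cm tank: time in the bottom/middle/top thirds of the
height, total distance, immobility (speed < 0.5 cm/s sustained ≥ 2 s), and
thigmotaxis (time within 2.4 cm of a wall).

**Synthetic behavior.** Turn streams are simulated from a two-state Markov
chain with `a = P(R | L)`, `b = P(R | R)` and Poisson turn timing; the
stationary right-turn probability is `a / (a + 1 − b)`. The package carries
the matching closed-form expected tetragram frequencies and their
overlap-aware sampling variance, so simulations can be checked against
theory at known tolerances, and an arm-path encoder so simulated fish
exercise the full event-log → turn-coding path.

## Worked example

```python
from fmpmaze import (CohortSpec, SessionConfig, simulate_cohort,
                     analyze_ymaze, cohort_class_summary)

spec = CohortSpec(n_left=5, n_right=5, n_non=8, random_seed=42)
cohort = simulate_cohort(spec)                      # event logs + ground truth
cfg = SessionConfig(random_seed=42)
metrics, results = analyze_ymaze(cohort.events, cfg)
print(metrics[["subject_id", "n_turns", "bias_R_pct",
               "alternation_score", "repetition_score", "label"]]
      .head(6).round(3).to_string(index=False))
print(cohort_class_summary(results).round(2).to_string(index=False))
```

prints

```
subject_id  n_turns  bias_R_pct  alternation_score  repetition_score        label
   fish000      345      50.145              0.278             0.056   non_biased
   fish001      346      48.555              0.309             0.047   non_biased
   fish002      337      51.039              0.311             0.027   non_biased
   fish003      236      73.305              0.060             0.279 right_biased
   fish004      445      50.112              0.224             0.070   non_biased
   fish005      356      75.281              0.082             0.337 right_biased

       label  count   pct
 left_biased      5 27.78
right_biased      5 27.78
  non_biased      8 44.44
```

Each row is one simulated hour-long session: `fish003` turned right on
73.3 % of 236 choices, so it is classed right-biased and — as expected for
a lateralized searcher — shows many repetition windows (0.279) and few
alternations (0.060), while the non-biased fish show the opposite pattern.
Here every recovered label matches the generator's ground truth.

The same pipeline runs from the shell:

```
fmpmaze simulate --seed 42 --out-dir data --n-left 5 --n-right 5 --n-non 8
fmpmaze analyze-ymaze --events data/arm_entries.csv --out-dir results
fmpmaze analyze-tank --front front.csv --top top.csv --out-dir results
fmpmaze analyze-conditioning --trajectory lane.csv --out-dir results
fmpmaze report --seed 42 --out-dir results     # full simulate+analyze bundle
```

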