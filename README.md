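# reachvigor

Simulation and analysis pipeline for a question in human threat
learning: **does Pavlovian threat conditioning invigorate subsequent
goal-directed action?**  In the paradigm this package models,
participants reach with a mouse toward circles on a screen; after a
learning phase in which one circle color (CS+) repeatedly precedes an
aversive shock while another (CS−) never does, reaches toward the CS+
become faster and more accelerated than reaches toward the CS− — even
though no shock can occur during reaching.  The strength of the
sympathetic response during learning (skin conductance) predicts the
size of that invigoration.

The package provides, as importable modules:

- **`reachvigor.design`** — trial schedules with the paradigm's
  counterbalancing and sequencing constraints (2 CS types × 3 target
  positions; 7-of-9 reinforcement per CS+ cell ⇒ 77.8% rate; a fixed
  six-trial lead-in; never more than two consecutive stimuli of the
  same type), plus screen geometry (px → cm).
- **`reachvigor.synth_motion`** — 100 Hz cursor trajectories with a
  minimum-jerk velocity profile: displacement fraction
  s(τ) = 10τ³ − 15τ⁴ + 6τ⁵, peak speed 1.875·D/T, peak acceleration
  (10/√3)·D/T².  A configurable CS+ vigor gain shortens CS+ movement
  times at test by a fraction g (default 3%), and a latent
  per-participant "reactivity" trait couples vigor to SCR amplitude.
- **`reachvigor.synth_scr`** — continuous skin-conductance traces
  (default 1250 Hz) with biexponential phasic responses, larger for
  CS+ (0.60 μS) than CS− (0.26 μS) on average.
- **`reachvigor.kinematics`** — per-trial scoring: central-difference
  speed/acceleration profiles; movement onset and offset at 2% of peak
  speed; reaction time from stimulus offset; endpoint accuracy;
  an automated screen for erratic trajectories; per-participant
  condition means.
- **`reachvigor.scr_scoring`** — decimation to 200 Hz and
  trough-to-peak scoring with the validity rules: trough onset
  0.5–4.5 s after CS onset, rise ≤ 5 s, amplitude > 0.02 μS; invalid
  trials scored zero with a machine-readable reason.
- **`reachvigor.stats`** — the within-subject suite: balanced
  repeated-measures ANOVA for any factor crossing with
  Greenhouse–Geisser correction (ε from the orthonormal-contrast
  covariance, Mauchly gate), Helmert contrasts on the pooled
  factor×participant error (df = 2(n−1)), paired t with
  d = t/√n and noncentral-t CIs, ηp² = F·df₁/(F·df₁+df₂) with
  noncentral-F pivot CIs, Cousineau–Morey within-subject CIs, and
  Pearson correlations with a single-pass ±3 SD residual screen.
- **`reachvigor.pipeline`** — `run_experiment(RunConfig)` for the full
  simulate → score → analyze chain (deterministic per config, with
  per-stage RNG streams), and `run_on_external(...)` to score and
  analyze externally supplied CSV data.

A thin CLI (`reachvigor run-all | simulate | score-kinematics |
score-scr | analyze | make-fixtures`) wraps the same functions.

## Worked example

`examples/05_full_experiment.py` simulates a 12-participant cohort
(learning phase plus both test phases) and runs the analysis:

```
SCR during learning, stimulus-type effect:
  F(1,11) = 34.49, p = 0.00011, ηp² = 0.76
  group means: CS+ 0.55 μS, CS− 0.30 μS

peak velocity at test, stimulus-type effect:
  F(1,11) = 16.27, p = 0.002, ηp² = 0.60

position effect on peak velocity: F = 624.6
```

The first block is the learning signature (larger phasic skin
conductance to the shock-paired stimulus), the second is the
invigoration effect (faster CS+ reaches at test), and the position
effect confirms the distance scaling of vigor — farther targets are
reached with higher peak velocity.  The other examples each
demonstrate one capability (schedules, reach simulation and scoring,
SCR scoring, the statistics suite) with a few lines of output.

## Data conventions

Coordinates are Cartesian pixels with the origin at screen centre and
y increasing upward; the reach starts at (0, −416) and targets sit at
(0, −96), (0, 64), (0, 224).  Trajectory logs are long-format CSV
(`participant, phase, trial, t_ms, x_px, y_px`); SCR traces are
(`t_s, conductance_uS`) plus an event table (`cs_onset_s, cs_type`);
schedules and all scored outputs are tidy CSV as documented in
`docs/methods.md`.
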