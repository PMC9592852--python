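# Methods

This note documents the models, scoring rules, numerical choices and
known limitations of the package, in the order the pipeline runs.

## Experimental design generator

The paradigm crosses stimulus type (CS+, CS−) with target position
(low, middle, high).  Reaching phases (baseline and the two test
phases) present each of the six cells `n_per_cell` times (default 20;
120 trials) in a uniformly shuffled order.  The stimulus is shown for
100 ms; pre-stimulus (1–1.5 s) and inter-trial (2–4 s) intervals are
drawn uniformly and carried in the schedule although they do not
affect scoring.

The Pavlovian learning phase presents 9 trials per cell (54 total) for
6 s each, with 12–14 s inter-trial intervals.  Reinforcement is 7 of 9
CS+ trials *within each position cell*, which yields the overall 21/27
= 77.8% rate; balancing per cell (rather than only overall) was chosen
because SCR is analyzed by position and unbalanced reinforcement would
confound the position factor.  The first six trials are a fixed
lead-in — one reinforced CS+ and one CS− at each position, shuffled —
and from trial seven on, no more than two consecutive stimuli of the
same type may occur; the cap is also enforced across the lead-in
boundary (the stricter of the two possible readings).

Sequencing is generated by seeded *constrained sequential sampling*:
the CS-type sequence is built left to right, choosing at each step
among the types that have trials remaining, do not extend the current
run beyond two, and leave a completable remainder, with probability
proportional to the remaining counts; position and reinforcement
labels are then shuffled within each type.  Plain rejection sampling of
whole orderings was rejected because a uniform shuffle of 24 + 24
trials satisfies the run cap with probability on the order of 10⁻⁵,
making an attempt-capped rejection loop unusable at the study size.
The sequential sampler is deterministic under the seed and never
dead-ends for feasible counts; an attempt cap is retained as a guard
and infeasible configurations raise `ScheduleInfeasibleError`.

Screen geometry assumes square pixels: cm/px = diagonal·2.54 / √(rx² +
ry²).  For the 43-inch 1920×1080 display this is 0.04958 cm/px, so the
64 px stimulus is 3.17 cm.  Coordinates are Cartesian, origin at
screen centre, y up; start point (0, −416) px.

## Trajectory generator

Each reach is a straight minimum-jerk transport from the start point
to the (noise-perturbed) target: displacement fraction s(τ) = 10τ³ −
15τ⁴ + 6τ⁵.  Minimum jerk was chosen because its closed-form extrema —
peak speed 1.875·D/T, peak acceleration (10/√3)·D/T² ≈ 5.7735·D/T² —
give the kinematic scorer exact oracles.  A trial consists of a
stationary latency period, the transport, and a stationary tail,
sampled at 100 Hz (the logger rate).  The cursor is invisible during
the reach in the real task, so a single uncorrected movement segment
is generated.

Parameter defaults (all configurable in `MotionParams`):

| parameter | default | rationale |
|---|---|---|
| movement time T (low/middle/high) | 0.140 / 0.142 / 0.150 s | noiseless peak speeds ≈ 212/313/398 cm/s, the group position means reported for this task |
| latency (mean ± SD) | 330 ± 40 ms | offset-referenced reaction time ≈ 230 ms as reported |
| CS+ vigor gain g | 0.03 | CS+ movement time scaled by (1−g); ratio of reported CS+/CS− velocities ≈ 1.02–1.03 |
| endpoint noise SD | 7 cm per axis | mean endpoint error ≈ 9 cm, matching the reported accuracy range (reaching without visual feedback is inaccurate) |
| path noise SD | 0.05 cm | hand tremor, applied only while moving — a resting mouse reports identical samples |
| anomaly rate | 0.012 | ≈ 1.4 erratic trials per 120-trial phase, the reported exclusion rate |

The vigor gain is implemented as movement-*time* scaling rather than
amplitude scaling, so CS+ reaches are faster and more accelerated but
not less accurate — the observed pattern.  It applies at test only:
invigoration is a consequence of learning and must be absent in the
pre-learning baseline phase (the pipeline's baseline ANOVA verifies
the null).  Injected anomalies are zig-zag reaches with four
alternating lateral excursions (≈2.5 cm), the positive case for the
anomaly screen.

Cohort simulation draws per-participant random effects: a log-normal
movement-time scale (SD 0.10), a vigor gain ~ Normal(g, 0.015), and a
standard-normal latent *reactivity* trait correlated 0.6 with the
vigor gain.  The same trait shifts the participant's CS+ SCR amplitude
(by 0.15 μS per SD), planting the cross-participant correlation
between learning-phase arousal and test-phase invigoration that the
correlation analysis recovers.

## SCR generator

The conductance signal is tonic level (5 μS) + random-walk drift
(0.005 μS/√s) + per-trial phasic responses + white sensor noise
(0.01 μS) shaped by a 4th-order 10 Hz low-pass emulating the
acquisition hardware filter.  The phasic kernel is the biexponential
e^(−t/θd) − e^(−t/θr), normalized to unit peak (peak time
ln(θd/θr)·θrθd/(θd−θr)); defaults θr = 0.75 s, θd = 3 s put the peak
1.39 s after the trough.  Response latency is 1.5 s after CS onset —
inside the 0.5–4.5 s validity window, so noiseless responses are
always scoreable.  Amplitudes are drawn per trial from Normal(μ_cs,
0.30) truncated at zero with μ = 0.60 μS (CS+) and 0.26 μS (CS−), the
group means reported for this paradigm.  Truncation raises the
realized CS− mean to ≈ 0.30 μS; the CS+ − CS− differential, which is
what the analyses test, is preserved.  An optional linear habituation
slope is exposed but off by default.

## Kinematic scoring

Velocity is computed per axis by central differences on the raw
samples (one-sided at the ends, via `numpy.gradient`); speed is the
2-D norm, and acceleration is the central difference of speed — so
"deceleration" is the signed minimum of the speed derivative, matching
the reported negative values.  No smoothing is applied by default:
100 Hz logger samples are coarse, and smoothing would bias the
closed-form oracles; an optional Savitzky–Golay window is exposed.

Movement onset is the first sample with speed ≥ 2% of the peak;
reaction time is onset time minus *stimulus offset* (the stimulus
lasts 100 ms), exactly as the source analyses define it; a config flag
(`rt_reference`) switches to onset-referencing.  The movement offset
is the first sample at or after the peak with speed ≤ 2% of the peak
(the final sample if speed never falls that low); restricting the
offset search to at/after the peak guarantees the onset crossing is
never reused.  Accuracy is the Euclidean distance (cm) from the cursor
at the offset sample to the target centre.  Acceleration extrema are
taken over [onset, offset].

At the study's fast movement times (~0.14 s) the 100 Hz grid puts
discretization error of roughly 1–2% on the extracted peak speed and
several percent on peak acceleration; the 2%-level oracle checks
therefore use slower noiseless probe movements (T = 0.4–0.5 s), where
the error is a few tenths of a percent.  The latency-recovery check
uses the fast defaults, because there the 2% crossing occurs within
one sample of movement onset.

The anomaly screen replaces the visual inspection used on the real
data: direction reversals along each axis are counted over monotone
position runs, ignoring excursions below 0.5 cm, and a trial is
flagged when either axis exceeds two reversals.  These defaults are
declared, seed-stable surrogates for human judgment, not claims about
which real trials would have been excluded.  Flagged trials are
excluded from condition means; a cell left empty reports NaN (never a
silent zero) and a warning.

## SCR scoring

The trace is decimated to 200 Hz with a polyphase anti-aliasing
resampler (`scipy.signal.resample_poly`, line padding); an optional
zero-phase 10 Hz Butterworth low-pass is available for recordings not
filtered at acquisition.  Scoring is trough-to-peak on discrete
extrema: peaks are local maxima with prominence ≥ half the amplitude
criterion; each peak's trough is the last sample achieving the minimum
between the previous peak (or the CS onset) and the peak, so a
flat-then-rising segment dates its trough to the start of the rise.

Validity rules, applied in order with the first failure recorded as
the zero-reason: trough onset within 0.5–4.5 s of CS onset (bounds
inclusive), trough-to-peak rise ≤ 5 s ("lasted for a maximum of 5 s"
is read as rise time, the convention of trough-to-peak scorers), and
amplitude strictly > 0.02 μS.  Invalid trials score zero and *enter
condition means as zeros* — they are data, not missing values.  Among
several qualifying deflections the largest amplitude wins, ties to the
earliest trough.

Drift robustness: a slow net-positive tonic drift leaves no local
minimum at a response's onset, which would date the trough to the
start of the scoring segment and zero-score a real response as
outside-window.  When the raw trough precedes the validity window but
the signal has risen by at most half the amplitude criterion (0.01 μS)
by the window start, the trough is re-dated to the last sample still
within that tolerance of the minimum.  A response genuinely beginning
before 0.5 s has risen well past the tolerance by then and is still
rejected.  This rule never fires on the noiseless oracle traces, whose
amplitude recovery is exact to within discretization (< 1%).

## Statistical suite

The repeated-measures ANOVA assumes a complete balanced within-subject
design on condition means (missing cells raise
`IncompleteDesignError`, naming the participant).  Sums of squares are
computed by inclusion–exclusion over marginal means; each effect is
tested against its own effect×participant interaction.  For effects
with ≥ 2 numerator df, Greenhouse–Geisser ε is computed from the
orthonormal-contrast transform of the between-condition covariance
(Kronecker contrasts for interactions), clamped to [1/df₁, 1], and the
correction is applied when Mauchly's test rejects at α = .05 — the
source analyses say only "whenever a violation occurred", so the
standard test at the conventional level was chosen; both corrected and
uncorrected p-values are always reported.  The implementation is
cross-checked against pingouin for one- and two-factor designs (which
is as far as pingouin goes; the three-factor test-phase design is
checked against a direct sums-of-squares oracle).

Helmert contrasts on the position factor (level 1 vs mean of 2 and 3;
level 2 vs 3) use the pooled factor×participant error mean square with
df = 2(n−1) — reverse-engineered from the reported t(66) at n = 34; a
per-contrast error option (df = n−1) is exposed.  Raw weights (1, −½,
−½) are used; any rescaling of the weights cancels in t (verified in
tests).

Paired tests report d = t/√n (difference-score standardization) with
95% CIs by noncentral-t inversion; ηp² = F·df₁/(F·df₁+df₂) with 90%
CIs by noncentral-F pivot inversion, converting the noncentrality
bound λ to η² = λ/(λ + df₁ + df₂ + 1) and truncating the lower bound
at 0.  The inversions use Brent's method to 10⁻⁸–10⁻¹⁰; the
noncentral-t bracket is limited to t ± 15 because scipy's nct CDF
underflows to NaN far in the tail (NaN is resolved by its limit).
Identical-by-construction identities (d ≡ t/√n; ηp² from SS equals the
F-based formula; 2-level RM ANOVA F ≡ paired t²) are asserted in the
test suite.

Descriptive within-subject CIs follow Cousineau normalization
(subtract the participant mean, add the grand mean) with the Morey
inflation √(M/(M−1)) for M cells.

Correlations between the per-participant CS+ − CS− differentials (SCR
at learning vs each kinematic measure at test, averaged over positions
and test phases first) use Pearson r after a *single-pass* residual
screen: a least-squares line is fit and points with |residual| > 3
residual SDs are removed once, mirroring the one-shot removal in the
source analyses; the removed indices are reported.  No
multiple-testing correction is applied anywhere — every test is
reported at its own two-sided p, with α = .05, matching the analysis
style this suite reproduces.

## Pipeline and reproducibility

A run is a pure function of `RunConfig`: the master seed is split via
`SeedSequence.spawn` into design/motion/SCR streams, so perturbing one
stage's parameters cannot ripple into another's draws.  The results
bundle carries provenance (seed, config hash) and reruns are
byte-identical.  `run_on_external` applies the identical scoring and
statistics to user-supplied CSVs and validates their schemas
column-by-column; with a single participant it raises the ANOVA's
incomplete-design error while the per-trial scoring functions remain
usable directly.

Problem sizes: the acceptance script and the end-to-end tests simulate
34-participant cohorts (the study's sample size) with the full trial
counts; replicate runs (100 cohorts for the detection-rate estimates)
synthesize SCR at 250 Hz rather than 1250 Hz, decimated to the same
200 Hz scoring rate — the phasic kernel is band-limited far below
either rate, so scoring is unaffected while the replicate loop stays
tractable.

## What the synthetic data do and do not show

The generator reproduces the *structure* of the paradigm — schedules
and constraints, distance-scaled minimum-jerk vigor, a
movement-time-based CS+ invigoration, event-related SCR with a CS+
amplitude advantage, participant heterogeneity with an SCR–vigor
coupling — and its defaults are anchored to the published group means.
It does not emulate: online movement corrections or submovements,
pixel quantization of the logger, SCR habituation dynamics (beyond an
optional linear decay), non-stationary arousal, or the true
between-participant distributions, which are unknown.  Passing
recovery tests therefore demonstrates that the scoring and inference
machinery detects effects of the planted form and size under realistic
noise — not that the real data would yield the same numbers.  Printed
peak-acceleration magnitudes in the source (tens of cm/s²) are
dimensionally inconsistent with true cm/s² for these movements (the
logger's native per-sample units are the likely cause); this package
computes true cm/s² and targets orderings and effect directions, not
those magnitudes.
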