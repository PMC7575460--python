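# Methods

`lwl` is an offline, testable implementation of a gaze-triggered
looking-while-listening (LWL) paradigm for measuring infants' lexical speed
of processing, together with the classic (predetermined-target) variant it
is compared against, the reaction-time extraction rules, the reliability and
validity statistics, and a generative simulator that provides ground truth
for every downstream stage.

## The paradigm

In a looking-while-listening trial two familiar pictures are shown side by
side and one of them (the *target*) is named. An infant who knows the word
shifts their gaze to the target. The *visual reaction time* (RT) is the
latency from target-word onset to the first fixation shift from the other
picture (the *distractor*) to the target. An RT exists only on
distractor-initial trials — trials where the infant happens to be looking at
the distractor when the word begins. In the classic design the target is
fixed in advance, so roughly half of all trials are target-initial and
yield no RT.

The gaze-triggered variant removes this loss: after a 2 s silent preview and
an exclamation ("Look!"), the first picture the infant fixates continuously
for 100 ms becomes the *distractor*, and the *other* picture is named at
that instant. Every triggered trial is distractor-initial by construction.

Bias correction keeps the design from letting a one-sided infant hear only
one label of a pair. The controller deviates from the trigger rule in two
cases, naming the fixated item itself:

1. **third-in-a-row** — the infant fixated the same item of the pair on the
   two preceding gaze-triggered trials and does so again;
2. **fourth trial** — on the pair's last gaze-triggered trial the target is
   whichever item restores an exact 2/2 label split.

With four gaze-triggered trials per pair this guarantees every item is
named exactly twice per condition; enumeration of all 16 possible
fixation sequences confirms it, and also that at most 2 trials per pair
(16 per session, half the gaze-triggered trials) can be bias-corrected.
Bias-corrected trials count as completed but yield no RT. If no trigger
fixation occurs within a set window the label is triggered manually; the
pair's least-labeled item (ties: a scheduled backup) is named, preserving
the balance guarantee.

### Session design

80 trials: 32 gaze-triggered + 32 original in alternating 8-trial blocks
(one trial per stimulus pair per block), plus 2 filler trials inserted into
each block — never first or last in a block, never adjacent. The stimulus
inventory is 8 fixed yoked pairs (16 items, 4 per category: food, animals,
clothes, toys); fillers use 4 separate items. Counterbalancing is exact per
schedule: each item is the predetermined target twice in the original
condition, each item of a pair appears on the left in exactly half of the
pair's appearances per condition, and the first condition alternates across
participants by parity. Pair order within a block is uniformly random
(the design constraints do not fix it). The session stops once the infant
fails to complete five trials in a row; a trial "fails" when total
on-screen looking over the whole trial is under 100 ms, mirroring the
analysis-side attention criterion.

### Trial timeline (ms, picture onset = 0)

| event | time |
|---|---|
| attention getter | ends at 0 after a 500 ms fixation (or manual advance) |
| silent preview | 0 – 2000 |
| exclamation | 2000 – 2000 + dur |
| trigger window (gaze-triggered) | exclamation offset + 5000 ms, then manual fallback |
| label onset | trigger time, or exclamation offset + 100 (original) |
| trial end | label onset + 2000 |

The 16 exclamation recordings are assigned fixed durations evenly spaced on
610–1120 ms, so original-condition label delays span 710–1220 ms after
exclamation onset. The length of the trigger window is a design choice
(nothing in the trial structure fixes it); 5 s accommodates the long tail
of naturally occurring trigger delays while keeping trials bounded.

## Analysis rules

* Fixations shorter than 100 ms are discarded before any analysis (closed
  threshold: exactly 100 ms is kept).
* A trial is **attended** if cumulative on-picture looking within 0–2000 ms
  after label onset reaches 100 ms.
* The **initial AOI** is the AOI of the fixation whose half-open interval
  covers the label-onset instant; if none covers it the trial yields no RT
  (the strictest reading — gaze is never imputed).
* **RT** = onset of the first target-AOI fixation after label onset,
  label-relative. Off-screen gaps between the distractor and target
  fixations do not invalidate the shift. Valid iff the trial is attended,
  distractor-initial, not bias-corrected, not manually triggered, and
  300 ≤ RT ≤ 1800 ms (earlier shifts cannot be reactions to the word; later
  ones are probably unrelated).
* Participants enter the comparison only with ≥ 1 valid RT in *both*
  conditions (`min_rt_trials` is configurable; 2 is the common choice in
  the wider literature).
* The per-condition yield measure is 100 × valid RT trials / completed
  experimental trials of that condition (fillers excluded).

## Statistics

* **Yield comparison**: one-sided paired t on the per-participant valid
  percentages (gaze-triggered predicted higher); t = mean(d)/(sd(d)/√n),
  df = n−1. Zero-variance differences degenerate to p ∈ {0, 0.5, 1} by the
  sign of the mean and are flagged.
* **Validity**: Spearman rank correlation between per-participant mean RTs
  across conditions. rho is the Pearson correlation of tie-averaged ranks,
  p from the t approximation, and the 95% CI from the Fisher z transform
  with se = 1/√(n−3) (a standard choice; the CI method is reported in the
  output so it can be swapped).
* **Split-half reliability**: per participant and condition, valid RTs are
  randomly split in half (odd counts: the surplus trial joins a random
  half, seed-controlled), each half averaged, and the half means
  rank-correlated across participants. Participants with fewer than 2 valid
  RTs are dropped and counted. The default is a single seeded split;
  `n_splits > 1` Fisher-z-averages several splits (a smoothed estimate,
  labeled as such).
* **Trial-order and word-knowledge effects**: the reference analysis is a
  mixed model `RT ~ x + (1|participant) + (1|target) + (1|target:participant)`.
  The primary implementation is a dependency-light two-stage approximation —
  an OLS slope (or known-minus-unknown mean difference) per participant,
  then a one-sample t across participants — which is well calibrated on
  null data (95% CIs cover zero at the nominal rate in the test suite). An
  adapter (`method="mixed"`) fits the crossed-random-effects model via
  statsmodels MixedLM variance components for exact replication.
* **Vocabulary**: Spearman correlation between cross-condition mean RT and
  the expressive (produced-words) vocabulary score.

## The simulator

Each synthetic infant draws: a latent mean shift latency
μ ~ Normal(950, 130) truncated at 400 ms (spanning the 600–1300 ms range of
published infant visual RTs at 18 months); per-trial attention probability
~ Beta(8, 2); fixation-bout dwells ~ Gamma(2, 300 ms) with 20–40 ms saccade
gaps and occasional off-screen excursions; per-pair object preferences
~ Beta(2, 2); and an expressive vocabulary
round(max(0, 200 − 0.15·(μ − 950) + Normal(0, 40))), so latency and
vocabulary are weakly negatively related (the empirical rank correlation of
measured RT with vocabulary comes out around −0.2, a modest association as
observed in this literature). Word knowledge is Bernoulli with probability
increasing logistically in vocabulary (≈ 2 of 16 items unknown at the mean).

A trial unfolds as alternating left/right bouts; gaze-triggered trials are
generated interactively against the controller so the label onset is the
actual trigger time. At label onset, a distractor-initial infant who knows
the word shifts to the target at latency 300 + LogNormal with the log-mean
chosen so that E[latency] = μ exactly (shape σ = 0.3); unknown words elicit
a shift with probability 0.3 at Uniform(300, 1800) ms. Target-initial
trials continue ordinary bout dynamics. Inattentive trials (probability
1 − p_attend) put under 100 ms of gaze on screen and fail both the
completion and attention criteria.

What the simulator does **not** emulate: raw 1000 Hz samples, saccade
kinematics, pupil size, blinks, calibration drift, anticipatory shifts,
learning or fatigue trends, and item-level difficulty differences. Passing
tests therefore demonstrate the correctness of the pipeline's logic and its
statistical calibration under a plausible generative model — not that real
infant data will show the same effect sizes. The simulated trial yields
(≈ 20 valid gaze-triggered vs ≈ 10 original trials per infant) are
deliberately only ordered and of similar magnitude to published yields, not
matched to them: infant inattention in the lab is harsher than the Beta(8,2)
default.

## Numerical and design choices

* Times are float milliseconds, trial-relative, picture onset = 0; all
  fixation intervals are half-open `[onset, offset)`, so a fixation ending
  exactly at label onset does not cover it and a point on an AOI's far edge
  is outside.
* The 100 ms trigger criterion means one *continuous* fixation: abutting
  same-AOI fixation records (zero gap) merge into one run; separated looks
  do not accumulate.
* A trigger fixation already in progress when the window opens counts only
  from the window start.
* The fourth-trial bias rule is implemented as exact balance enforcement,
  the only reading consistent with every item being heard equally often and
  with the 16-trial cap on corrections. A literal alternative
  (`fourth_trial_rule="repeat_previous"`: deviate only when the fourth
  fixation repeats the third trial's) is available for sensitivity
  analysis, without any claim that it matches the original apparatus.
* All randomness flows from `numpy` `SeedSequence`s keyed by (seed,
  participant index, stream tag), so schedules, infants and gaze streams
  are independently reproducible; equal seeds give byte-identical outputs.
* Degenerate inputs are flagged, not hidden: constant vectors give
  flagged NaN correlations, empty conditions give undefined percentages,
  and report sections that cannot be computed carry an
  `insufficient_n` marker.

## Problem sizes

The test suite runs cohorts of 43 simulated infants (20 replicates for the
replication-level checks), one 200-infant cohort for the trial-yield claim,
10,000-trial randomized fixtures for the brute-force oracle comparisons,
and 100–200 replicate null simulations for calibration; the whole suite
completes in about a minute on one core. `scripts/acceptance.py` analyzes
one 43-infant cohort in a few seconds.

## Known limitations

* The two-stage effect estimates approximate, and do not reproduce, a
  crossed mixed model's shrinkage; with very unbalanced trial counts the
  mixed adapter is preferable.
* The EyeLink ASCII reader consumes only `EFIX`/`MSG` lines with the
  four trial tags; it is not a general ASC parser.
* The controller is an offline replayer with millisecond bookkeeping; it
  does not model display/audio latencies of a real-time loop.
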