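# Methods

`codecide` analyzes embodied collective decisions: small groups (2–4
people) each privately judge which of four targets is correct, rate their
confidence (1–4), and then negotiate a consensus by dragging avatars
across a shared 29 × 29 cm arena until everyone rests inside the same
8 cm-diameter target circle. The package covers the whole chain — data
model and filtering, an agent-based session generator, trajectory feature
extraction, cluster-based permutation statistics, influence and
majority/minority analyses, regression models, and explicit/tacit
metacognitive sensitivity. This note records the models, the parameter
choices, and the places where the design was genuinely open.

## Data model and coordinate conventions

Coordinates are screen-centered, in cm, y up. The four targets sit on
the arena diagonals at 15 cm from the center, numbered counter-clockwise
from the upper right; start positions lie on the same diagonals at
4.4 cm, one slot per participant in numbering order. The geometry gives
only distances from the center, so this angular convention is a package
choice and is used consistently by the simulator and all analyses.

Trial validity follows three rules, applied in order: (1) a trial is
dropped when any member's private answer or confidence is missing; (2) a
session is dropped entirely when any member is missing in more than half
of its trials; (3) a trial is dropped when a trajectory teleports (any
inter-sample displacement above a configurable 5 cm threshold) or leaves
the arena. Rule 3 replaces manual visual screening of movement
artifacts with a reproducible automatic criterion; 5 cm in one sample is
far beyond what finger-dragging can produce at the default 100 Hz.
Filtering is idempotent, and missing consensus (a trial truncated before
agreement) is stored as a missing consensus target and excluded from all
influence analyses.

Sessions are stored as one directory per session: `session.json`
(identity, geometry, metadata), `trials.csv` (one row per trial ×
participant) and `trajectories.csv` (long table of t/x/y samples).
Writes are byte-stable for a fixed session. A named format-profile hook
in `read_session` leaves room for reader dialects beyond this canonical
layout.

## The session generator

The generator is a behavioral mimic, not a cognitive-process model: no
evidence accumulation, no haptic coupling, no collision between avatars.
Its purpose is to produce corpora with the statistical structure the
analysis is supposed to detect, so that every downstream stage can be
tested end to end without human data. Defaults describe the study
conditions the pipeline targets: 64 trials per session, four difficulty
levels with 16 trials each interleaved in balanced shuffled blocks, and
a corpus of 17/14/13 groups of size 2/3/4.

**Private answers.** An agent answers correctly with probability
`competence[difficulty]`; the default population curve (0.72, 0.66,
0.60, 0.54) falls 0.06 per difficulty step, matching the accuracy
gradient the analysis should recover, and errors are uniform over the
three wrong targets. Per-agent competence offsets (SD 0.08) create the
better- and worse-than-average members that the best-individual and
average-accuracy analyses need. Sessions flagged as trained get a
+0.04 competence shift.

**Confidence.** A latent evidence signal sits at +½ for correct and −½
for incorrect answers with SD `meta_noise` and is discretized at the
marginal quartiles into ratings 1–4, so ratings are roughly uniform and
the correct/incorrect overlap is governed by one parameter. The default
`meta_noise = 2.6` puts the explicit second-order ROC area near 0.60
(chance 0.5, perfect 1.0); `meta_noise → 0` gives 1.0, `→ ∞` gives 0.5.

**Movement.** Each agent heads straight toward its current goal at
`speed_gain × confidence` cm/s plus Gaussian jitter (SD 0.3 cm/s per
sample) and halts when its avatar center crosses the goal circle; the
trial ends when all centers rest inside the same circle, or with a
missing consensus at 15 s. The capture rule — center inside the circle,
with no extra tolerance — makes the noise-free consensus time a closed
form used as a test oracle.

**Opinion revision.** At every sample an opposed agent revises its goal
with hazard

    social_weight × (weighted opposers at the plurality other target)
    ÷ (1 + weighted own support) × (5 − confidence) ÷ persistence,

multiplied by `majority_bonus` when the opposing subgroup is a strict
majority. An opposing agent still traveling exerts only
`arrival_weight` (default 0.1) of the pull of one resting at its target.
The two weighting terms are deliberate refinements of a bare
opposer-count hazard: diluting pull by own support makes a backed agent
resist a lone dissenter, and discounting travelers creates the standoff
that makes prevailing minorities slow. Without them, minority- and
majority-influence trials had indistinguishable consensus times, because
revisions happened while everyone was still near the center and durations
were purely travel-dominated.

**Calibration.** `speed_gain = 2.0`, `social_weight = 0.7`,
`majority_bonus = 3.0`, `arrival_weight = 0.1` were fixed once against
the target duration and prevalence profile (mean trial duration a few
seconds, nearly all trials under the 10 s analysis horizon, majority
influence more common than minority influence in groups of three) and
then left alone. The simulated duration distribution lacks the long
deadlock tail of real groups (simulated SD ≈ 2 s), and the generator
produces no invalid answers by default — filtering is exercised through
constructed fixtures. Those are the main senses in which passing tests
do not certify behavior on real data; the others are the absence of
communicative intent, arena-edge effects, and any within-trial change of
confidence.

## Trajectory features

Each trajectory is linearly resampled onto a uniform grid (derivatives
come after resampling, so uneven native sampling is harmless) and
reduced to eight series on the first 10 s of the trial: {distance,
speed, relative distance, relative speed} × {correct target, preferred
target}. Trials shorter than the horizon hold their final value
(recorded in `padded_from`); longer ones are truncated. There is no
time normalization.

* Distance is Euclidean, normalized by its value at t₀, so every series
  starts at 1 and a consensus-correct trial ends within
  (capture radius ÷ start distance) of 0. A trajectory starting on the
  reference point has no defined normalization and errors out.
* Speed is −dẑ/dt by central differences (one-sided at the ends),
  positive while approaching the reference, then smoothed with a 0.5 s
  centered moving average whose window shrinks symmetrically at the
  boundaries — chosen so the initial-speed region is not biased by
  artificial padding. The unsmoothed derivative conserves the total
  distance drop (∫r dt = ẑ(0) − ẑ(end) to discretization error); the
  smoothing redistributes a few 10⁻³ of that mass near the start where
  curvature is high, which is why the conservation test runs
  pre-smoothing.
* Relative series subtract the mean of the other participants' series
  *for the same reference point*. For the preferred-target reference
  this means the others' distances to **this** participant's preferred
  target, not to their own — easy to get wrong, asserted in tests.

## Cluster-based permutation statistics

Trajectory series from consensus-correct trials are grouped into the
eight cells of a 2 (correct) × 4 (confidence) design, equalized by
seeded subsampling to the smallest cell, and tested pointwise with a
balanced two-way fixed-effects ANOVA (correct df 1, confidence df 3,
interaction df 3, error df n − 8). Runs of adjacent samples whose F
exceeds the parametric p = 0.05 quantile form clusters scored by summed
F; the (correct, confidence) label pairs are then permuted jointly
(1000 times by default) to build a null distribution per effect.

The null statistic is the per-permutation **maximum** cluster sum, the
construction MNE-Python's cluster permutation test uses; agreement with
MNE on observed clusters is covered by a cross-check test. An
alternative that pools every surrogate cluster into the null is kept
behind `null_mode="pooled"` for comparison, but it is strongly
anticonservative — on 200 i.i.d. Gaussian datasets it retained at least
one cluster in roughly half the datasets per effect, versus 3–6% for the
max-statistic null — and is not used by the pipeline. P-values use the
add-one convention (1 + #null ≥ observed)/(1 + n_null) so they are never
exactly zero; clusters with p < 0.05 are retained. Time points where
all values are identical get F = 0; a between-cell difference with zero
within-cell variance gets F = +∞ with a warning. Trajectories are
treated as exchangeable units across participants and group sizes; no
within-participant permutation restriction is applied, a caveat when
trials from one person are strongly dependent.

## Session metrics

Influence is 1 when a participant's private answer equals the consensus
decision. A consensus trial is *unanimous* when all members led,
*majority* when more than half but not all did, *minority* when exactly
one of three or one of four did, and *half* for 2-of-4. Scalar movement
predictors: initial speed is the mean speed magnitude over the first
second (magnitude, not signed speed toward a target, so it can act as a
target-agnostic confidence proxy); speed variability is the SD of the
speed magnitude over the first two seconds; onset time is the first
moment Euclidean displacement from the start reaches 0.5 cm (missing if
never). Speed magnitudes use the same resampling and 0.5 s smoothing as
the directional series. All three are invariant to rigid rotations of
the arena.

Obstruction is a geometric proxy: indicator 1 when, at trial start,
another avatar's disc intersects the straight corridor of width 2 ×
avatar radius from the participant's start to any target center
(distance from the other's center to the segment ≤ 2 × avatar radius).

Leader−follower differential series average, per leading-subgroup-size
stratum and on the common grid, the mean leader minus mean follower raw
distance (cm) to the consensus target, over non-unanimous consensus
trials; negative values mean leaders are closer. Accuracy summaries
report per-participant, mean, best and group accuracy, collective
benefit (group minus best member), and first/second-half splits at the
midpoint of the retained trial order.

## Regression models

Models are declared as `ModelSpec` (response, fixed-effects formula,
optional random-intercept grouping factor, family) and fitted to the
flat analysis table:

* Gaussian mixed models (accuracy analyses, random session intercept)
  are fitted by REML via statsmodels `MixedLM`, with a fallback chain of
  optimizers because a boundary random-intercept variance can make one
  optimizer's path singular.
* The binomial random-intercept GLMM (influence analyses, random
  participant intercept) is fitted by maximum likelihood with 15-point
  Gauss–Hermite quadrature over the per-group random-effect integral —
  the same marginal-likelihood construction `lme4::glmer` uses — with
  Wald covariance from the numerical Hessian. A test verifies agreement
  with `glmer` (estimates and SEs to ~3 decimals) on a shared dataset.
  Non-convergence is reported as a flag, never an exception; a constant
  or perfectly separated binomial response raises a diagnostic error.
* Simple regressions (consensus time on number of leaders; tacit on
  explicit Aroc; Aroc on window and group size) are ordinary least
  squares.

Confidence and difficulty enter as numeric covariates with raw
(uncentered) interactions; coefficient uncertainty is a Wald standard
error. Term-level tests are marginal Wald chi-squares on each term's
coefficient block (equal to the squared Wald z for single-column terms).
Reported model SDs are interpreted as standard errors throughout.

## Metacognitive sensitivity

With four confidence levels there are three binary criteria (rating ≥ 2,
≥ 3, ≥ 4); plotting TPR against FPR at those criteria plus the corners
traces the second-order ROC, and its trapezoidal area is the Aroc. The
implementation is property-tested against the tie-aware rank statistic
P(rating_correct > rating_incorrect) + ½P(tie) by full enumeration, to
1e-12, and is invariant under strictly increasing relabelings.

Tacit ratings replace explicit confidence with movement measures: each
preferred-target series (distance, speed, relative distance, relative
speed) is averaged within ten 1-s windows, pooled per participant ×
window across trials, and binned into four equal-width bins between the
pool's min and max. Distance-type measures are inverted before binning
so a higher rating always means more evidence of being correct; a value
exactly on an interior bin edge goes to the upper bin, and the maximum
gets bin 4. Degenerate pools (min = max) and single-class participants
produce flagged missing entries rather than numbers.

Each (measure ×) group-size × window cell is tested against chance with
the one-sided one-sample Wilcoxon signed-rank test of the participants'
Arocs against 0.5 — one group against a constant is the one-sample
setting, although the two-sample rank-sum name is sometimes attached to
this comparison; the output labels the test used. All tested cells
enter one Benjamini–Hochberg correction at q = 0.05; cells with fewer
than five participants are skipped with a note.

## Reproducibility and problem sizes

Every entry point takes one integer seed that fans out into per-stage
child seeds via `numpy.random.SeedSequence`, and every CLI run writes a
manifest (options, seeds, package version). Test problem sizes are
chosen to exercise each property at the smallest scale where it is
statistically decidable: 16-trial sessions at 50 Hz for unit fixtures,
~500-trial corpora for simulator signatures, 200 null datasets of
8 × 20 trajectories × 300 samples at 500 permutations for the
cluster-test calibration, and 100 replicates of ~36 participants × 20
trials for GLMM coverage. The acceptance script runs the full
study-scale corpus (44 sessions × 64 trials at 100 Hz) and thins the
cluster-test grid by a factor of 5 (20 ms resolution).

## Known limitations

* The simulator's duration distribution is lighter-tailed than real
  groups', and its group-accuracy gain over the mean individual is
  smaller than in human data; signature tests therefore check directions
  and orderings, not magnitudes.
* The obstruction indicator is a start-of-trial corridor heuristic, not
  a dynamic interference model.
* Cluster permutation treats trajectories as exchangeable across
  participants; dependence within a participant is ignored.
* Tacit-rating bins are computed per participant × window over all
  retained trials, after trial filtering.
* No reader profile exists yet for externally deposited datasets; only
  the canonical CSV layout is supported.
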