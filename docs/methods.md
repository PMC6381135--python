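# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the known limitations of `ipdcohort`.

## Game model

Two players simultaneously choose C or D each round for 30 rounds.  Payoffs
are percent profits with the standard Prisoner's Dilemma ordering
T=40 > R=30 > P=20 > S=10; the payoff table is symmetric (each player's
payoff depends on own/other action the same way), and the joint payoff is
maximal only under mutual cooperation.  The computer opponent plays
tit-for-two-tats on the participant's action sequence: it opens cooperatively
and defects only after the participant defects twice in a row, returning to
cooperation as soon as the participant cooperates once.  Independently of
that state, it defects in the final `endgame_defect_rounds` (default 2)
rounds.  Feedback labels (happy/neutral/sad) are a deterministic function of
the participant's action and the 2×2 condition: a happy face follows
cooperation only under positive feedback, a sad face follows defection only
under negative feedback; the labels do not influence any simulated agent
(see the generator section).

## Strategy automata

Strategies are deterministic finite automata over the joint history,
conditioned on the *opponent's* actions only.  The catalogue covers ALLC,
ALLD, TFT, TF2T, TF3T, 2TFT, 2TF2T, Grim, Grim2, Grim3 and DTFT, encoded by
three machine families:

- constants (ALLC, ALLD);
- sliding-window punishers: defect iff the opponent defected within the last
  *k* rounds (TFT k=1, 2TFT k=2, DTFT = k=1 with a defecting first move);
- consecutive-defection triggers with an explicit punishment phase: enter
  punishment after *n* consecutive opponent defections; leave it after one
  opponent cooperation (TF2T n=2, TF3T n=3), after two consecutive opponent
  cooperations (2TF2T, a three-phase content/punishing/re-earning automaton),
  or never (Grim n=1, Grim2, Grim3).

For the one-cooperation-forgiveness machines the phase formulation is
provably equivalent to "defect iff the last *n* opponent moves are all D";
the tests exploit this by checking every automaton exhaustively against an
independently coded verbal-rule interpreter on all joint histories of length
≤ 4.  The four-strategy preset `table6` (TF3T, 2TF2T, Grim, ALLD) is the
headline estimation set — one representative each of the cooperative,
forgiving, unforgiving and defective families; `full` is the default for new
analyses.

## Tremble likelihood and per-subject estimation

A subject nominally following strategy *s* executes the prescribed action
with probability β and the opposite with 1−β, independently across rounds.
Prescriptions are conditioned on the *realized* joint history (including the
subject's own trembles), so the per-strategy likelihood reduces to
β^m (1−β)^(T−m) with m the match count.  The error scale is reported as
γ = 1 / logit(β); γ → 0 is perfect compliance and γ < 1 (β > 0.73) is
conventionally read as the strategy set approximating the subject well.

Per subject, γ̂ maximizes the *uniform-mixture* log-likelihood
log (1/S) Σₛ β^mₛ (1−β)^(T−mₛ) by bounded scalar search on γ ∈ [0.01, 5]
(compliance β ∈ (0.55, 0.9933…)) with absolute tolerance 1e−6, guarded by a
64-point geometric scan (the mixture can be bimodal in γ) and explicit
boundary evaluation.  For short sessions the likelihood can be exactly flat
in γ (e.g. T=1 with one matching and one mismatching strategy); likelihood
ties within 1e−9 are broken toward the smallest γ — the least-tremble
explanation.  Subject-level strategy weights are the normalized per-strategy
likelihoods at γ̂, i.e. the posterior under a uniform prior over the set.  A
literal per-subject mixture MLE is degenerate (its optimum always sits on a
simplex vertex), which is why the posterior-weight estimator is the default;
the vertex (argmax, ties split equally) estimator is available and all
outputs state which was used.

Cohort frequencies are the arithmetic mean of subject weights and the
reported γ is the mean of the per-subject γ̂.  Uncertainty comes from a
participant bootstrap (default B=1000): SE is the standard deviation of the
resampled cohort means, the p-value against frequency = 0 is the one-sided
upper normal approximation, and 2.5/97.5 percentile intervals are also
emitted.  The population-level mixture MLE (SFEM) maximizes
Σᵢ log Σₛ φₛ β^mᵢₛ (1−β)^(Tᵢ−mᵢₛ) over the simplex φ and a common γ by EM
(posteriors → φ update → posterior-weighted match rate → β update), with
seeded multi-start; it serves as a cross-check on the subject-average
estimator.

### Identifiability limitation (important)

Against this computer opponent, strategy separation comes almost entirely
from rounds where the opponent defects — and the tit-for-two-tats computer
defects only after the subject defects twice in a row (or in the scripted
final two rounds, which affect round-31+ prescriptions only, i.e. never
within the game).  A subject playing any cooperative strategy at β = 0.9
triggers no computer punishment in roughly 75 % of sessions, in which case
ALLC, TF3T and 2TF2T prescribe *identical* sequences, their likelihoods tie
exactly, and the posterior necessarily splits the weight equally among them.
Cohort-level frequencies for these three strategies are therefore strongly
shrunk toward each other (ALLD, Grim and γ itself are well identified: Grim
separates through the scripted endgame, because it is the only cooperative
strategy that answers the round-29 computer defection).  Simulation at the
default conditions recovers {ALLD 0.55, Grim 0.07} and β within ±0.01–0.03,
but redistributes {2TF2T 0.22, TF3T 0.15, ALLC 0.01} to roughly 0.12–0.13
each.  This is a property of the experimental design, not of the estimator:
the population-level SFEM likelihood is equally flat across the cooperative
block.  Consistently, in such designs only the defective strategy's
frequency is sharply bounded away from zero while cooperative-strategy
estimates carry large standard errors.  Longer games, noisier opponents, or
opponents that occasionally defect on their own initiative would break the
equivalence class.

## Psychometric scoring

The 40-item psychopathy short form is scored on a 1–4 ordinal scale into
eight 5-item subscales; factor scores are item sums after flipping
reverse-keyed items (r → 5 − r), with fearless dominance = 3 subscales
(15 items), self-centred impulsivity = 4 subscales (20 items), and
coldheartedness = 1 subscale (5 items); their sum is the aggregate
psychopathy measure.  The shipped item→subscale map is a synthetic stand-in
with exactly this shape and a fixed reverse-key pattern — the published
assignment is part of the copyrighted instrument — and is replaceable by a
CSV with columns `item_id, subscale, factor, reverse_keyed`.  Narcissism is
the proportion of narcissism-consistent choices over 16 forced-choice items;
a configurable scale factor (default 1 = raw proportion) is exposed because
the published descriptives (max 0.33) imply an unstated rescaling that we do
not guess.  Participants with an inconsistent-responding (IRS-10) score at or
above the cutoff (default 13) are excluded before analysis; no missing-item
imputation is performed anywhere (complete-case analysis).  Cronbach's α is
provided as a descriptive utility only.

## Synthetic cohort generator

The generator emulates the study conditions; its defaults are fixed and are
not tuning knobs:

- n = 192 participants, exactly balanced over condition (1–4) × game version
  (deception/non-deception) whenever n is divisible by 8 (cells tiled, then
  seed-shuffled);
- trait marginals matching the published sample moments: fearless dominance
  (34.67, 7.51) on [17, 56], self-centred impulsivity (30.91, 5.89) on
  [16, 49], coldheartedness (10.78, 2.97) on [5, 20], narcissism
  (0.08, 0.09) on [0, 0.33]; gender 112/192 female; `maximise` on 1–5 with
  mean 4.26, SD 0.90;
- strategy mix {ALLD 0.55, 2TF2T 0.22, TF3T 0.15, Grim 0.07, ALLC 0.01} —
  the cohort-level estimates the recovery experiments must reproduce — and
  tremble β = 0.9, the compliance level used in the stated recovery
  conditions;
- trembles i.i.d. per round and insensitive to condition/feedback (matching
  the finding of no feedback effect on cooperation); a trait→strategy
  softmax tilt is available to create known trait–strategy correlations for
  power/recovery studies, and is off by default.

Numerical choices for the marginals: the three factor scores use truncated
normals whose parent (μ, σ) are *solved* (least squares on the truncated
moments) so that the post-truncation mean/SD equal the targets — naive
parametrization by the targets would shift the mean and shrink the SD
noticeably.  The narcissism moments are infeasible for any truncated normal
on [0, 0.33] (the family is log-concave; its best attainable SD at mean 0.08
is ≈ 0.075), so narcissism uses a moment-matched scaled beta
(a ≈ 0.36, b ≈ 1.11), which also reproduces the spike at zero typical of
short-form narcissism scores.  The ordinal `maximise` rating uses the
maximum-entropy pmf on {1..5} with the target mean and SD (exponential
family in k and k²).  An optional Gaussian copula couples the traits and
`maximise` with the published correlation matrix (Pearson correlations after
the marginal transforms are mildly attenuated, e.g. 0.40 → ≈ 0.37); marginals
are unchanged.  IRS-10 scores for generated participants are drawn below the
exclusion cutoff (rounded truncated normal, mean 6, SD 3 on [0, 12]) — the
generator produces the post-exclusion cohort; attrition behaviour is
exercised separately in tests with constructed cohorts.

What the generator does *not* emulate: response times, dropout, learning or
within-game strategy switching, feedback-sensitive trembles, and any joint
trait distribution beyond the optional copula.  Passing recovery tests on
synthetic cohorts therefore demonstrates correctness of the estimation
machinery under the stated generative model, not the behavioural validity of
that model for real participants.

## Regressions and model selection

The two dependent variables are the overall cooperation fraction and the CaC
count — cooperations immediately following the participant's *own* previous
cooperation (the opponent-conditioned variant exists under a separate name
for sensitivity analysis).  The CaC proportion handed to regressions divides
by rounds−1 by default (`total`); the `conditional` normalization (divide by
own previous cooperations) is selectable and outputs are labelled.  Three
families are fitted to each DV: an ordinary linear model on the proportion
scale, a binomial-logit GLM on (successes, trials), and a beta-binomial
regression with logit-linear mean and a common precision parameter fitted by
direct likelihood maximization (L-BFGS-B with a Nelder–Mead polish;
standard errors from a finite-difference Hessian).  Family selection uses
repeated k-fold cross-validation over participants (k=5, 10 repeats by
default, seeded; folds depend only on the seed and n, so row order is
irrelevant), scoring the MSE of the predicted mean response on the
proportion scale — the only loss directly comparable across the three
families; exact ties resolve to the earlier candidate.  The interaction
analysis regresses each DV on four separately-fitted interaction blocks
(game version × psychopathy sum, positive × negative × sum, positive × sum,
negative × sum), always controlling for gender, game version, maximise,
narcissism, the two condition flags and the psychopathy main effect.
Significance markers throughout: ``***`` < 0.001, ``**`` < 0.01, ``*`` <
0.05, ``.`` < 0.1 (two-sided).

## Problem sizes used in the checks

Exhaustive automaton and oracle-equivalence checks enumerate all joint
histories up to length 4 (341 histories × 11 strategies; 8 500 tremble-fit
instances over ≤ 3-strategy subsets).  Recovery experiments use cohorts of
200 participants × 30 rounds; moment-fidelity checks use n = 5 000 draws at a
3-standard-error tolerance; the regression type-I calibration uses 500
replications of n = 500 with a trait-independent binomial DV.  These sizes
give binomial/Monte-Carlo standard errors comfortably inside the asserted
tolerances.

## Degenerate inputs and edge policies

Unknown or duplicated strategy names raise configuration errors listing the
valid catalogue; histories with unequal own/opponent lengths, invalid action
symbols, or invalid condition/gender codes are rejected at validation; a
constant variable makes its correlations NaN and is flagged rather than
silently dropped; a constant psychopathy aggregate aborts the interaction
regressions (the product terms would be collinear); all-zero likelihoods
(impossible within the γ bracket, but guarded) yield uniform weights with a
degeneracy flag; non-converged fits are returned flagged, never hidden.
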