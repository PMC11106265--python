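# Methods

`riskreact` implements a two-arm analysis of how people weigh probability
versus reward information in risky choice, and how that weighting relates to
which choice outcomes they preferentially represent while deciding.  The
package covers the full chain — task construction, choice modelling with
hierarchical fitting, stimulus decoding from sensor epochs, reactivation
prioritization, second-level permutation inference, and a response-time
probe analogue — together with a synthetic-cohort generator so every stage
can be validated against planted ground truth.

## Task model

Each trial offers a gamble against a safe outcome OS.  Accepting yields
gamble outcome O1 with probability p (signalled by one of four pretrained
probability stimuli, p ∈ {.2, .4, .6, .8}) or O2 with probability 1−p.  One
gamble outcome per trial — the *trigger* — carries a large absolute point
value; the other carries points near zero; the safe value lies between.
Blocks alternate gain and loss framing (four of each); all base points are
negated on loss blocks.  Per-trial noise is a common uniform(0, 20) draw
added to all three outcomes plus independent uniform(0, 5) draws per outcome
(both negated on loss trials).

The generator crosses trigger levels {45, 65, 75} × safe levels
{20, 32, 44} × both trigger assignments × four probability stimuli, each
exact configuration twice, yielding 288 decision trials in 8 blocks with
every probability stimulus appearing equally often per block.  This is the
unique fully crossed 3×3 grid among the printed reward levels in which every
pair satisfies |trigger| > |safe|; an alternative printed level set
(triggers {47.5, 60, 75}, safes {20, 40, 60, 80}) is selectable but admits
only 7 valid pairs and hence a smaller (224-trial) balanced design, which
the design metadata flags.  Catch trials (no probability stimulus; excluded
from all fits) are added on top at 10% of presented trials (32 on top of
288).

## Choice models

Five models map a trial to an acceptance probability:

- **Expected value**: `logistic(β·[p·R_O1 + (1−p)·R_O2 − R_OS])`.
- **Additive heuristic**: `logistic(β₀ + β_prob·[P_better − P_worse] +
  β_rew·[R*_trig/2 − R*_safe])`, where β₀ is a gain/loss-specific
  intercept, "better/worse" order the gamble outcomes by points, and R* is
  each reward after subtracting the non-trigger outcome's realized reward.
  β_prob and β_rew are the *choice probability weight* and *choice reward
  weight* used throughout the second-level analyses.
- **Prospect theory**: log-odds-linear probability weighting
  `w(p) = δp^γ/(δp^γ + (1−p)^γ)` with power utility (`x^α_gain` for gains,
  `−|x|^α_loss` for losses) inside the expected-value rule.  At
  δ = γ = α_gain = α_loss = 1 it reduces exactly to the EV model.
- **Probability / utility-weighted sampling**: the decision maker draws S
  samples (S ~ ordered probit over {1..7}, binned as
  Φ((s+½−n)/c) − Φ((s−½−n)/c) with c = 2 and free center n) from a proposal
  q over the gamble outcomes — q ∝ P (probability sampling) or
  q ∝ P·|v(R)−v(R_OS)| (utility-weighted) — and accepts iff the
  importance-weighted estimate of the gamble-minus-safe utility difference
  is positive (ties split 50/50).  The acceptance probability marginalizes
  exactly over (S, #O1 draws).  Two numerical points matter: the estimate's
  normalizer is implemented count-based, `n₁w₁ + (S−n₁)w₂`; and under the
  utility-weighted proposal `|w·Δv|` is identical across outcomes by
  construction, so balanced compositions are exact mathematical ties —
  these are detected at a relative tolerance of 1e−9 before the sign is
  taken, rather than being left to floating-point rounding.

Likelihood contributions clamp p to [1e−12, 1−1e−12].

## Hierarchical fitting and model comparison

Parameters are fit per subject by MAP under independent group-level
Gaussian priors on transformed parameters (log for positivity-constrained
β, α, δ, γ; identity for the additive weights and the sampling center n,
which the likelihood clips to [0, 8]).  EM alternates (E) per-subject MAP
(L-BFGS; five seeded random restarts at the first iteration, warm starts
after) with a Laplace covariance from a central-difference Hessian, and (M)
prior moment updates from the subject posteriors, with a variance floor of
1e−6.  Convergence is declared when the approximate log marginal likelihood
changes by less than 1e−6 (default cap 200 iterations).

Models are compared by iBIC: −2·Σ_s log p̂(data_s | prior) +
2k·log(N choices), with the subject marginal likelihood p̂ estimated from
2000 seeded prior draws and k the number of group-level means.  The EV and
additive models use a vectorized logistic-regression likelihood path; the
nonlinear models evaluate trial by trial.

## Decoding

Localizer epochs (sensors × 10-ms bins × events) are scaled by a single
global scalar — the 95th percentile of absolute values over the whole
training block — which is stored and reused on test data.  Per outcome
stimulus (O1, O2, OS) and train bin τ, a lasso logistic classifier
discriminates that stimulus's events from the other six stimuli plus an
equal number of null (inter-trial) samples drawn without replacement
(matched by default to the total stimulus-example count; matching positives
alone is selectable).  Classifiers are scikit-learn liblinear fits with
C = 1/(nλ), seeded, with the intercept effectively unpenalized
(intercept_scaling = 100).  The λ grid defaults to
{.0005, .001, .002, .004, .008} with .002 as the no-selection default.

Cross-validation is 7-fold, stratified by stimulus label.  An event counts
as correct when its own outcome classifier emits the highest activation
probability (argmax ties break by the fixed order O1 < O2 < OS); scoring
every (train bin, test bin) pair yields a temporal-generalization accuracy
matrix, and λ* maximizes the mean matched-bin (diagonal) accuracy.  A
shuffled-label null threshold is the 95th percentile of peak diagonal CV
accuracy over label permutations.

## Reactivation prioritization

The trained bank (train bins τ ≥ 20 ms) is applied to task epochs aligned
to probability-stimulus onset (test bins τ′ from 0 ms), after dividing by
the stored training scale, giving reactivation probabilities
RP[trial, outcome, τ, τ′].  Task bins at or after the trial's response are
censored.  Per (τ, τ′), ordinary least squares predicts
ΔRP = RP_O1 − RP_O2 from an intercept, ΔP = P_O1 − P_O2 and
Δ|R| = |R_O1| − |R_O2| over valid non-catch trials — the two slopes are the
subject's *neural probability prioritization* and *neural reward
prioritization*; the safe classifier's mean RP over valid trials is kept
alongside.  Cells with fewer than 3 valid trials or collinear regressors
are undefined (NaN) and excluded downstream.  Regressors stay on their
natural scales.

## Second-level inference

Per map cell, the subject-level metric is regressed on a behavioral
covariate (a fitted choice weight, or an impulsivity questionnaire score)
by robust regression: bisquare IRLS (tuning constant 4.685), scale
re-estimated each iteration as median|r|/0.6745, slope standard error from
the converged weighted fit, se² = [Σw r²/(n−2)]·[(X'WX)⁻¹]_slope.  The
IRLS is hand-vectorized across permutations and cells (closed-form
two-parameter WLS updates) so the permutation machinery runs at scale on
one CPU; its slopes agree with statsmodels' Tukey-bisquare RLM to ~1e−5 and
the t statistics differ only by the standard-error convention, which is
irrelevant to permutation inference.  Capping IRLS at 30 iterations
(tolerance 1e−6) leaves t maps stable to ~1e−3.

The t map is smoothed with a 2-D Gaussian kernel (σ = 1.5 bins, truncated
at 4σ, renormalized over in-bounds defined cells so constants are
preserved and NaN cells stay NaN).  Family-wise error over the map is
controlled by a max-statistic permutation test: the covariate-to-subject
assignment is permuted (seeded; 5000 permutations at full scale), the
smoothed map recomputed, and its extremum recorded — the maximum for
predicted-positive couplings, the minimum for predicted-negative ones.
p_FWE = (1 + #{null extrema at least as extreme})/(n_perm + 1), which
includes the identity assignment and so is bounded below by 1/(n_perm+1)
and exactly valid under exchangeability.  Cells undefined for any subject
are dropped before permutation; partially missing cells are fit pairwise in
the observed map when at least 5 subjects remain.

One-tailed Spearman tests use the t approximation:
t = r√(n−2)/√(1−r²) on average ranks with n−2 degrees of freedom.

## Response-time probe arm

On probe trials an arrowhead appears on one outcome stimulus after the
probability stimulus and detection latency indexes that stimulus's active
representation.  Per subject, log RT is regressed (OLS) on the
probed-minus-nonprobed probability difference and absolute-reward
difference, over gamble-probe trials only; RTs outside [0.15 s, 5 s] are
dropped as anticipations/lapses (configurable).  Negative slopes mean
faster detection of more probable / higher-reward outcomes.  The
per-subject slopes are linked to the additive model's choice weights by
one-tailed (negative) Spearman tests.  Fits are per subject (no pooling),
matching the between-subject correlations the analysis reports.

## Synthetic cohorts

`CohortSpec` defaults mirror the study's scale: 19 subjects × 288 decision
trials (sensor arm), 88 subjects (RT arm), 120 sensors, 50 localizer bins
(10–500 ms) and 51 task bins (0–500 ms), 3 localizer blocks × 20
presentations of each of the 7 stimuli plus an equal number of null
segments.  Each stimulus has a fixed random Gaussian sensor pattern under a
Gaussian temporal envelope (center 200 ms, width 50 ms) at amplitude
`pattern_snr` (default 2) over unit noise.  Task epochs inject the outcome
patterns at a task-time locus (250 ms, width 50 ms) with gain
`base + slope_prob·(P − .5) + slope_rew·(|R| − mean|R|)/30`; choice RTs are
shifted-lognormal (0.25 s + lognormal(log .5, .35)), so later task bins are
partially censored, as in real data.

Population choice weights are β_prob ~ N(4, 1.5²) and
β_rew ~ N(.06, .025²) with frame intercepts N(±.2, .5²) — chosen so the
probability and reward terms move the decision variable by comparable
(±2-logit) amounts over the design's ranges, giving realistic mixed
strategies.  Between-subject couplings set each subject's neural slopes to
`a·z(weight) + noise` (defaults a = 1, noise sd .25), RT slopes to
`−b·z(weight) + noise` (b = .15, noise sd .05 on log-RT per unit contrast),
and the impulsivity covariate to `60 − 5·slope_prob + N(0, 3²)`.

What the generator does **not** emulate: realistic sensor covariance and
spatial autocorrelation, oscillatory/temporal autocorrelation in noise,
eye-movement or motion artifacts, drifting decoding accuracy across
sessions, non-stationary strategies, or any forward-model head geometry.
Passing tests therefore demonstrate that the estimators recover the
statistical structure they assume — linear reactivation prioritization,
log-linear RT effects, exchangeable subjects under the null — not that
they are robust to physiological confounds.

## Problem sizes used in tests and the acceptance script

Behavioral fitting and model recovery run at full scale (19 subjects × 288
trials; 10 replicate cohorts).  Sensor-level arms run at a reduced scale
chosen to keep a complete replicate under ~10 s: 8–10 subjects, 16 sensors,
20-ms bins over 10–300 ms (localizer) and 0–300 ms (task), 2 blocks × 10
presentations.  Permutation-FWE calibration uses 400 replicate null
cohorts of 12 subjects with 8×8 maps at 500 permutations; end-to-end
planted-effect recovery uses 5 coupled and 12 null replicate cohorts at
500 permutations.  The Monte-Carlo cross-check of the sampling models uses
10⁶ episodes.

## Known limitations

- The Laplace/EM scheme can understate posterior uncertainty for strongly
  skewed subject posteriors (e.g., near-deterministic responders); the
  prior variance floor guards degenerate collapse but is not a substitute
  for full posterior inference.
- iBIC's Monte-Carlo marginal likelihood has ~1-unit jitter at 2000 draws;
  model comparisons closer than a few units should increase `n_draws`.
- The robust-regression t uses a weighted-least-squares standard error
  rather than a leverage-corrected robust covariance; inference relies on
  the permutation distribution, not on t's nominal null.
- The sampling models' likelihood surface is multimodal in n; recovery of
  n is not guaranteed and is not claimed.
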