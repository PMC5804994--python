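# Methods

This note documents the models, the numerical choices and the limits of the
`sleepconjoint` pipeline: what is being simulated, why the defaults are what
they are, and what passing tests do and do not establish.

## The scenario space

A scenario is a point in a product space of 17 categorical parameters, each
belonging to one of five time periods (day before, pre-sleep, during sleep,
upon waking, day after). Sixteen parameters have 3 ordered options; wake
after sleep onset (WASO) has 5, giving `3^16 × 5 = 215,233,605` scenarios.
Level indices are 1-based throughout; level 1 — the first option listed in
the packaged definition — is the reference level for every parameter in
every weight block and model coding.

The packaged definition corrects one transcription defect in the source
instrument's options table: physiological arousal lists "I felt very
uncomfortable" for both its first and third option; the third is encoded as
"I felt very comfortable", consistent with the instrument's own exemplar
narrative of a preferred night ("I felt very comfortable lying in bed").

Narrative rendering weaves the selected option phrases into a first-person
account with a fixed connective template, in period order. The connective
text is a package constant patterned on the instrument's exemplar sentences;
it is presentation, not a scientific claim — the original study does not
print its full template, and whether its connectives varied by scenario is
unknown. Every option phrase appears verbatim in the rendering, which makes
rendering injective over scenarios.

## The MCMCP engine

Markov Chain Monte Carlo with People treats a respondent's binary choice as
the accept/reject step of a Markov chain over scenarios:

1. a chain holds a current scenario `s`;
2. the mutation kernel proposes `s'` by redrawing `k` parameters;
3. the respondent chooses between `s` and `s'`; the chosen scenario becomes
   the chain's next state.

With a Luce/logit chooser, `P(choose s') = σ(U(s') − U(s))`, step 3 is the
Barker acceptance rule, and because the proposal is symmetric the chain's
stationary distribution is exactly `p(s) ∝ exp(U(s))`. Chains attached to
the "worse" question sample `∝ exp(−U)`, since the respondent chooses the
scenario judged worse. This stationarity is the engine's core correctness
property and is verified in total variation against the exact enumerated
Boltzmann distribution on reduced (2–3 parameter) spaces.

**Mutation kernel.** `k` is drawn from a truncated geometric pmf
`p(k) ∝ (1−r)^(k−1) r` on `{1..17}` — the minimal standard reading of a
"truncated geometric" proposal; the rate `r` is solved by bisection
(`scipy.optimize.brentq`, |E[k] − target| < 1e-9) so that `E[k] = 4.6`, the
study's stated mean. The mean is monotone in `r`, from `(1+K)/2` (uniform
limit) down to 1, so attainable targets lie in `[1, (1+K)/2)`; on reduced
test spaces (K = 2–3) the default 4.6 is unattainable and fixtures use a
target of 1.3–1.5. The `k` changed parameters are chosen uniformly without
replacement and each is redrawn uniformly over its *other* levels, so the
realized Hamming distance equals `k` exactly. A config switch
(`allow_self_level`) admits the alternative reading in which a "changed"
parameter may redraw its current level; it defaults off.

**Session structure.** 48 trials per participant: 4 chains × 12 trials,
2 chains per question type. Chains are interleaved by blocks — each block
visits every chain once in a freshly shuffled order — so the sequential
structure is not apparent. Presentation order (current state vs proposal
shown first) is randomized and recorded per trial to support an order-effect
intercept downstream. Chain states persist in the chain group and carry over
to the next participant; two consecutive 12-trial sessions on a group are
state-equivalent to one 24-trial run under the same random stream.

**Randomness.** One root seed is split via `numpy.random.SeedSequence` into
named streams (cohort, chain initialisation, sessions); reruns are
byte-identical.

## The synthetic cohort

Respondents are simulated agents with:

* a ground-truth `UtilityWeights`: part-worths per (parameter, level) on the
  log-odds scale with level 1 pinned at 0; optional pairwise interaction
  weights restricted to the 4 during-sleep × 7 upon-waking/day-after
  crossings; optional question-type shifts (applied on "worse" trials only)
  and sleeper-group shifts;
* a logistic noise scale (default 1, which identifies weights with log
  odds);
* a compliance flag. Noncompliant agents choose uniformly at random and
  answer fast (log-normal response times with median 8 s vs 35 s for
  compliant agents, σ = 0.35 on the log scale); only the < 20 s
  mean-response-time rule is used to exclude them.

The default demonstration weights are *synthetic*: they follow the
qualitative importance ordering reported for sleep-quality judgment (total
sleep time largest, then feeling refreshed and day-after mood; day-before
parameters near zero) with one WASO × refreshed interaction and one
refreshed × question shift, but they are this package's invention, not
estimates from any study's data.

Cohort traits (age, BMI, ISI, typical SOL/WASO/TST) are drawn from
group-specific truncated normal distributions centred on the study's printed
group summaries, with ISI truncated to the group cut-offs (good ≤ 7,
poor ≥ 8). The default design places exactly 7 noncompliant participants,
seeded into positions other than first-in-group, so the default run
reproduces the study's participant flow deterministically: 100 enrolled,
7 fast-responder and 6 first-in-chain exclusions, 87 retained, 4176 choices.
A participant matching both exclusion rules is counted once as a fast
responder (the overlap never occurs under the defaults; the tie-break is
ours).

What the generator does *not* emulate: individual differences in weights
(all agents share the ground truth, mirroring the design's own assumption),
learning or fatigue across trials, reading-time dependence on narrative
content, and the categorical demographics (sex, ethnicity, language) of the
original cohort.

## Convergence diagnostics

Scenario chains are coded numerically as level indices (one coordinate per
parameter) — one defensible reading, since the source analysis does not say
how categorical states were fed to its diagnostic. The univariate statistic
is the variance-based corrected potential scale reduction factor

    R̂² = ((n−1)/n + B/(nW)) · (df+3)/(df+1),

with `W` the mean within-chain variance, `B = n·Var(chain means)`, and `df`
estimated by method of moments; identical chains give the estimator's lower
bound `√((n−1)/n)`. The multivariate PSRF uses the largest generalised
eigenvalue: `MPSRF² = (n−1)/n + λ_max(W⁻¹B)/n`, without the df correction,
so the d = 1 case reduces to the univariate form up to that factor. The
interval-based variant of the diagnostic exists; this package implements the
variance-based form only.

Burn-in is selected in whole-participant blocks (the study's removal unit):
the smallest `b` such that the post-`b` MPSRF falls below the threshold
(default 1.2), computed per question type (better/worse chains target
different distributions) and pooled across sleeper groups; both are
switches. A floor of one participant per chain is enforced — the first
participant's trials seed the chains (states retained, records dropped).

A caveat at the study's own scale: with 12 chains per question stratum and
17 coordinates, the between-chain covariance has rank ≤ 11, and the largest
generalised eigenvalue is upward-biased at short chain lengths (~190
states). Per-parameter univariate R̂ values sit well below 1.1 on stationary
runs, but the multivariate statistic can exceed 1.2 there even though
nothing is wrong. The stationary-floor acceptance check therefore runs the
same chain layout with a larger cohort (250 compliant participants,
~490 states per chain), where the bias is immaterial and the rule returns
the floor across seeds.

## The choice model

Each trial is one row in the *first-shown* frame: the response is whether
the first-shown scenario was judged the better night, scenario columns are
`features(first) − features(second)`, and a constant column captures primacy
(the tendency to pick whichever scenario was read first). In this frame,
physically flipping presentation order in every trial negates only the
primacy coefficient, and relabelling the a/b bookkeeping is a no-op.

Features are treatment-coded indicators (level 1 reference; block width =
levels − 1, 36 columns), plus within-scenario products for the 28
during-sleep × next-day pairs (widths `(L_i−1)(L_j−1)`, 140 columns).
Sleeper-type and question-type enter only as modifiers — their main effects
are constant within a trial and cancel from the differenced design — coded
as (good = 1) × main-difference and (worse = 1) × main-difference blocks
(36 + 36 columns). Full canonical width: 249. Fig-4-style comparisons of
exponentiated part-worth differences are coding-invariant, so the treatment
coding is presentation only.

**Fitting** is straight Newton/IRLS maximum likelihood, written in-package
because its behaviour is specified (relative-deviance tolerance 1e-8, at
most 100 iterations, step-halving on deviance increases). Separation is
flagged when any |coefficient| > 15; the default response is a refit with an
L2 penalty of 1e-6 (flag retained). `statsmodels.Logit` serves as an
independent oracle in the test suite (coefficients to 1e-6), never as the
implementation.

**Joint LRTs** follow the source analysis: the restricted model drops a
parameter's main block *and every* interaction column involving it
(scenario-pair, sleeper, question; e.g. 68 columns for WASO), and the
deviance difference is referred to χ² with df = dropped columns, at a fixed
α = 0.01 with no further multiplicity correction and no small-sample
adjustment. Restricted fits are warm-started from the full fit's surviving
coefficients; the statistic is clipped at 0 against round-off.

**BIC ranking** fits, per parameter (or per time period), a model with only
that entity's main-effect block(s) plus the primacy intercept, and ranks by
`BIC = −2LL + k ln n` ascending, `k` counting that model's coefficients.

**Best-preferred scenario**: per parameter, the level with the maximal
estimated part-worth (reference counts as 0; ties break to the lower level
index), rendered with only the jointly-significant parameters highlighted.

## Problem sizes and test design

The heavy checks use these scales, chosen to make Monte-Carlo error small
relative to the quantities tested: kernel-mean estimation at 10^5 proposals
(±0.05 band); stationarity at 4 × 10^4 post-burn-in trials on a 27-state
space (total-variation bound 0.05); part-worth recovery at 2 × 10^4 iid
choice trials (rank correlation and Wald coverage); type-I calibration of
the joint LRT at 1000 replicates of n = 4176 (99% binomial acceptance
region around α = 0.01). Calibration and recovery use independent uniform
scenario pairs rather than chained MCMCP trials so the design is
well-conditioned; the chained design's statistical behaviour is covered
separately by the stationarity and diagnostic checks.

One calibration finding deserves emphasis. In a lean model (main effects
only, 37 columns) the joint LRT is exactly calibrated at n = 4176
(empirical size 0.010 at α = 0.01 over 300 replicates). In the full
249-column canonical model, however, the null statistic for a 34-df joint
test has mean ≈ 36.7 rather than 34 — the classic Bartlett-type inflation
that appears when the coefficient count is an appreciable fraction of the
observation count (249/4176 ≈ 6%) — which inflates the 1% tail to roughly
0.015–0.025. The fitted statistics agree with an independent implementation
to < 1e-4, so this is a property of the χ² reference at this model size,
not of the optimizer. Since the method's own convention is the plain χ²
upper tail with no small-sample correction, significance calls near the
α = 0.01 boundary in the full model should be read with this mild
anticonservatism in mind; the corresponding study-scale calibration test in
the acceptance suite documents the effect by failing the nominal binomial
band.

## Known limitations

* All inference assumes no individual differences in weights — the same
  simplification the carry-over design itself makes.
* The logistic model is evaluated on data generated by the matching Luce
  rule; robustness to misspecified choice noise is untested.
* The multivariate PSRF is unreliable when chain count ≤ dimension and
  chains are short (see above); prefer the per-parameter univariate table
  at small scales.
* Printed-summary t statistics can only be reproduced to the rounding of
  the published means and SDs (≈1%).
* No genetic-algorithm elicitation, adaptive stopping, FDR control, or
  mixed-effects/random-utility extensions.
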