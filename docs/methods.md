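# Methods

`trustgame` implements a generative account of behaviour in the
10-round investor–trustee trust game, exhaustive-search likelihood
fitting of that model, model-free behavioural indices, a synthetic
longitudinal cohort generator, and the mixed-model statistical stages
used to analyse such cohorts.  This note records the model definition,
the numerical conventions, and the design choices made where the
design was genuinely open.

## Game

Each round the investor holds a fresh endowment of 20 coins and sends
`a_I ∈ {0, 5, 10, 15, 20}` (raw 0–20 integer investments are binned as
[0,2]→0, [3,7]→5, [8,12]→10, [13,17]→15, [18,20]→20).  The transfer is
tripled; the trustee returns one of five fractions
`f ∈ {0, 1/6, 1/3, 1/2, 2/3}` of `3·a_I` (a zero investment forces a
zero repayment).  Round payoffs are `χ_I = (20 − a_I) + a_T` and
`χ_T = 3·a_I − a_T`.  All legal repayments are multiples of 2.5 coins
and therefore exact in binary floating point; fractions are also
exposed as exact rationals.  Coins are not carried across rounds.

## Agent model

A subject is a seven-parameter interactive-POMDP agent
`Θ = (α, ω, k, P, ζ, q, β)` on the discrete grids

| parameter | grid | meaning |
|---|---|---|
| α  | 0, 0.4, 1 | inequality aversion (Fehr–Schmidt, advantageous side) |
| ω  | 0.4 … 1.8 step 0.2 | social risk aversion: value of coins kept |
| k  | 0 … 4 | theory-of-mind level |
| P  | 1 … 4 | planning horizon (future rounds considered) |
| ζ  | 0, 0.25, 0.5, 0.75, 1 | irritability (shift rate toward retaliation) |
| q  | 0 … 4 | irritation awareness (prior on partner's ζ) |
| β  | 1/4, 1/3, 1/2, 1 | softmax inverse temperature |

Utilities: investor `u_I = ω(20 − a_I) + a_T − α·max(χ_I − χ_T, 0)`;
trustee `u_T = χ_T − α·max(χ_T − χ_I, 0)`.  A fully averse (α = 1)
trustee's myopic optimum is the payoff-equalizing fraction, which is
what makes α the behavioural signature of trustworthiness.  The
trustee carries a static assumption `b_T(ω)` about the investor's risk
aversion (default 1).

**Beliefs.**  Agents hold Dirichlet pseudo-counts over the partner's α
(prior (1,1,1)) and over the partner's ζ (prior set by q), updated
after each complete round with the approximate rule
`A_new = A_old + p(o | type)` where `p(o | type)` is the probability of
the observed partner action under the level-(k−1) partner model of
that type.  Investors do not update the α belief from responses to
investments of 5 or fewer (an investment of 5 equalizes payoffs under
every fraction, so responses to it carry no inequality signal); the
ζ belief updates on any round in which the partner had a real choice.
The q → prior mapping is: q = 0 pins the ζ belief to 0 with updating
disabled ("ignorant"); q = 1…4 set counts proportional to `r^j` over
the five ζ levels with `r = 1/3, 1, 3, 9` ("unlikely" … "certain"),
normalized to a total count of 5.  These vectors are a package choice
(only the five setting names are fixed by the modelling tradition) and
are overridable.

**Irritation.**  Each agent tracks a mixture weight `w ∈ [0, 1]`.
When the partner's observed action falls strictly below the agent's
belief-based expectation of it, `w ← min(w + ζ, 1)`; strictly above,
`w ← max(w − ζ, 0)`; ties leave `w` unchanged.  Choice probabilities
are the mixture

    P[a] = (1 − w) · softmax_β(Q)  +  w · P_irritated[a]

where the irritated policy is myopic (no planning), inequality-blind
(α = 0), level −1, with risk aversion raised to `max(ω, 1)` and the
same β.  Expectations are computed with monetary action values
(`a_T` conditional on the current `a_I` for repayments, `a_I` for
investments), from the pre-observation belief state.

**Level-k recursion.**  A level-k agent predicts its partner with a
mixture of level-(k−1) agents over the α and ζ belief atoms, each
mixed with the irritated policy according to the tracked partner
irritation weight per hypothesised ζ.  Level −1 is static and
non-learning: a softmax over immediate utility, with the investor
evaluating repayments against a uniform assumption over the five
fractions (the maximum-entropy static assumption; it also fixes the
static expectation used for irritation triggers at k = 0: 10 coins for
investments, `a_I` coins for repayments).

**Planning.**  Action values follow a finite-horizon Bellman backup
over `min(P, rounds left)` future rounds: partner responses are drawn
from the current partner-model mixture, belief and partner-irritation
states transition inside the planning tree exactly as they do after
real observations, and continuation values are softmax-policy
expectations of the next round's Q values.  Future utilities are
undiscounted; the horizon truncates at round 10.

Two structural choices bound the recursion (both are package design
choices; the modelling tradition does not pin them down):

1. *Nested partner models plan one round ahead.*  Only the subject
   itself plans `min(P, rounds left)` ahead; every model-of-a-model
   plans exactly one round while still learning.  Unbounded
   inheritance of P makes the likelihood exponentially expensive in k
   with no qualitative change in behaviour at these grid sizes; a
   one-step-planning trustee model still repays strategically, which
   is what keeps k behaviourally meaningful.  With an
   irritation-ignorant subject (q = 0) the one-step trustee model
   collapses onto the static one — k is then identified only through
   q > 0 channels at k = 1, and through learning partner models from
   k = 2 on.
2. *Agents do not anticipate their own irritation.*  The irritated
   mixture applies at choice time; inside the planning tree the agent
   assumes it will act rationally, while fully anticipating the
   partner's irritation dynamics (so it can avoid provoking them).
   This keeps Q independent of ζ and w.

Belief updates happen at the end of each complete round; a trustee
choosing at round t therefore conditions on beliefs formed through
round t−1 plus the current investment.

## Likelihood, fitting, model comparison

The trajectory likelihood covers, by default, all 20 actions of a
game: the subject's 10 actions under the subject model plus the
partner's 10 actions under the subject's belief-weighted partner-model
mixture (`both_players` scope; an `investor_only` scope is available).
This scope is what makes the uniform-random benchmark score
`20·ln 5 ≈ 32.19` nats on games without zero investments; a forced
response to a zero investment contributes `ln 1 = 0`, which makes the
random model's likelihood trajectory-dependent when zero investments
occur.  Natural logarithms are used throughout.

Fitting is an exhaustive search over the discrete grid; ties (within
1e−9 nats) are counted and broken by ascending lexicographic order
over (α, ω, k, P, ζ, q, β).  The full grid has
3·8·5·4·5·5·4 = 48,000 points; desk-scale work uses reduced grids
(k ≤ 1, P ≤ 2) that still nest every fixed value of the reduced model
variants.  The comparison set is: M1 (all 7 parameters free), M2
(ζ = 0, q = 0), M3 (M2 + ω = 1, β = 1/3), M4 (M3 + k = 0), and M5
(uniform-random, 0 parameters).  Models are ranked by the average
Draper BIC

    BIC = NLL + (p/2) · (ln 10 − ln 2π)

with p the free-parameter count and n = 10 the per-role action count.

## Synthetic cohort

`generate_cohort` draws an accelerated longitudinal design: baseline
ages uniform on 14–24, a second visit after `N(1.48, 0.29)` years
(clipped to 0.99–2.6), balanced effect-coded sex, and a standard-normal
latent adversity score.  Structure injected by default:

* latent ω = 0.8 − 0.03·(cross-sectional age) − 0.08·(longitudinal
  age) + noise (sd 0.15), snapped to the ω grid — risk aversion
  declines with age both between and within persons, so trust rises;
* ζ drawn from a softmax over the ζ grid whose logits increase with
  adversity (slope 0.8 per SD per grid step) — adversity raises
  irritability;
* three waves of CFQ-like friendship scores
  `50 + 1·wave + 0.3·(round-1 trust − 10) − 2·adversity +
  0.15·trust·wave + 0.10·trust·wave·adversity + subject RE (sd 5) +
  noise (sd 3)` — baseline trust predicts the trajectory of peer
  relations, more strongly under adversity.

The default partner is a replayed repayment-fraction schedule drawn
per game (fractions weighted 0.10/0.15/0.30/0.30/0.15 over
0, 1/6, 1/3, 1/2, 2/3), emulating mostly-reciprocating adult trustees
with occasional exploitative and generous rounds; both below- and
above-expectation events occur, which is what keeps ω and ζ
identifiable.  A fully agent-based trustee is available
(`TrusteeConfig(mode="agent")`; default parameters: a trustworthy but
irritable level-0 learner, α = 1, k = 0, P = 1, ζ = 0.25, q = 2,
β = 1/3).  Generator truth values for k are kept at {0, 1} and P at
{1, 2} — the problem sizes at which a full cohort simulates in
seconds-to-minutes; the fitting machinery itself accepts the full
grids.

What the generator does **not** emulate: attrition beyond random
dropout, practice/retest effects, the empirical adult-trustee
algorithm (unpublished), IQ/SES covariates, and any non-uniform age
distribution.  Passing tests on these cohorts therefore validate the
estimation and statistical machinery under the assumed structure, not
the empirical claims of any particular dataset.

## Parameter recovery

`recovery_experiment` simulates agents at known grid points, refits
them, and reports exact/adjacent recovery rates and confusion
matrices.  The recovery grid uses β = 1 (least stochastic), q = 2, and
ω ∈ {0.4, 0.6, 0.8, 1.0} — the range over which expected investment
falls from ~17 coins to ~0, so risk aversion is identified by
behaviour; agents with ω ≥ 1 invest almost nothing, which is itself
the identifying signature.  Irritability is scored as a binary
ζ > 0 vs ζ = 0 classification: a ζ = 0.5 agent that never experiences
a below-expectation round is indistinguishable from ζ = 0 by
construction, so classification accuracy, not exact recovery, is the
meaningful summary.

## Statistical stages

*Age decomposition*: cross-sectional age = participant mean age minus
the mean of participant means; longitudinal age = visit age minus the
participant mean.  `age = sample mean + cross-sectional +
longitudinal` holds exactly.

*Adversity factor*: first principal component of subscale totals
standardized to mean 0/sd 1 (sample sd, ddof = 1), sign-oriented so
the mean loading of negative-experience subscales is positive.  Scores
are invariant to affine rescaling of any subscale.

*Mixed models*: linear mixed models with subject random intercepts
(random slopes behind a flag), REML via statsmodels, continuous
predictors centred, effect-coded binary covariates (sex ±0.5).
Fixed-effect tests use t statistics with residual degrees of freedom
(observations minus fixed-effect parameters).  This approximation is
mildly conservative for within-person effects in two-visit designs:
in calibration runs (200 cohorts of 200 subjects) the 95% CI for the
longitudinal-age slope covers the injected value ~95–99% of the time,
and the estimate is unbiased to Monte-Carlo precision.  Exact
replication of any specific statistics package's df recipe
(e.g. Satterthwaite) is out of scope; calibration is checked by
simulation instead.  Quadratic age terms are excluded by default and
available via the model-term lists.

## Numerical conventions

* Exact float comparisons for irritation triggers (all monetary values
  are multiples of 2.5, expectations are generic floats; exact ties
  occur only in forced-move rounds, where they are intended).
* Softmax computed with max-subtraction; probabilities are strictly
  positive, so NLLs are finite for every legal trajectory (+inf is
  reserved for degenerate user-supplied policies).
* Memoization caches (partner policies, state transitions, Q values)
  are keyed on exact nested belief-state tuples; cached and uncached
  evaluations agree to better than 1e−12 (tested), and caches are
  cleared per subject to bound memory.
* Grid search is serial and deterministic; tie-breaking is fixed, so
  refits are bit-identical.
* Mixed-model REML optimisation tries lbfgs, then bfgs, powell and
  Nelder–Mead; small samples with high-order interactions can make a
  single optimiser's Hessian step singular, and the fallback chain
  makes the fits robust without changing converged solutions.

## Known limitations

* k ≥ 2 agents are supported but expensive (minutes per decision at
  P ≥ 2); desk-scale analyses restrict truth values to k ≤ 1.
* The irritated investor policy with ω ≤ 1 is near-uniform rather than
  strictly zero-investing (its utility is flat at ω′ = 1 under the
  uniform-fraction assumption); retaliation is therefore most visible
  in low-ω (trusting) agents, and directional tests condition on that.
* The likelihood treats the partner's actions through the subject's
  partner model; it is a model of the subject's beliefs, not of the
  actual partner algorithm.
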