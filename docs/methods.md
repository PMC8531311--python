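# Methods

## Task model

The simulated experiment has two 210-trial blocks, one per outcome domain
(gain, loss).  Five stimuli per block: two distinct sure-zero options
(`Z1`, `Z2` — separate stimuli, hence separate action values, sharing an
outcome distribution), a sure ±10 (`T10`), a sure ±20 (`W20`), and a risky
option (`R`) paying 0 or ±20 with probability 0.5.  Outcomes are coded in
units of 10: gains in {0, 1, 2}, losses in {0, −1, −2}.  Every unordered
pair of options appears 20 times per block except {R, T10} — the
risk-preference probe, where both options have equal expected value — which
appears 30 times (9×20 + 30 = 210).  Within a pair's presentations the
left/right placement alternates exactly; the 210-trial multiset is then
shuffled uniformly (the run-length structure is unconstrained).  Block
order alternates gain-first/loss-first across simulated subjects.

Out of scope by design: stimulus rendering, response timing, missed-response
penalties, and payout bookkeeping.  The data reader drops rows with an
empty choice or outcome field, which is how missed responses in real data
are expected to be flagged.

## Learning models

All variants are delta-rule learners with softmax choice over the two
presented options only.  Values start at 0 and reset between blocks (the
blocks use different stimuli).  The subjective outcome is the coded value
with the large outcome weighted: +2 → 2κ_G, −2 → −2κ_L; 0 and ±1 pass
through.  The learning rate is selected by the sign of the prediction
error; a zero prediction error performs no update (and therefore needs no
rate selection).  Model variants cross three elaborations — PE-sign-split
learning rates, the utility weight κ, and domain splits of any parameter
kind — giving free-parameter counts 2, 3, 3, 4, 5, 6, 5, 8.

Parameter scales: learning rates live in (0, 1) via a sigmoid; β and κ are
positive via an exponential.  κ's transform is a package choice (positivity,
symmetric with β's treatment).  A diagnostic variant with an identity-scale
β (negative values admissible) exists to check that fitted choice behavior
is value-guided rather than anti-value.

An emergent property worth knowing: in the gain domain negative prediction
errors arise almost only on the risky option (sure options converge onto
their outcomes from below), so α_N(gain) — and symmetrically α_P(loss) —
is identified mostly by risky-option trials.  This is a consequence of the
outcome structure, not a separate mechanism.

## Hierarchical fitting

Type-II maximum likelihood with independent Gaussian priors per raw-scale
parameter.  E-step: per-subject MAP by L-BFGS from the prior mean, the
previous iteration's mode (warm start), and four prior-shaped restarts
whose standard-normal offsets are drawn once per fit and mapped through
the *current* prior — this keeps the E-step a deterministic function of
the prior, so the convergence trace is not jittered by fresh draws.
Curvature is a central finite-difference Hessian (step 1e-3), ridged from
1e-6 upward until positive definite.  M-step: moment matching,
mean ← avg(mode), var ← avg(mode² + diag H⁻¹) − mean², floored at 1e-6.

Initialization: raw means 0, variances 4 (diffuse).  Convergence is
monitored on the Laplace approximation of the marginal log likelihood; the
tolerance (default 0.01) and the divergence slack are **per subject** —
the lml and its Laplace approximation error both scale with cohort size,
and at n = 100 the fixed-point oscillation of the approximate trace
exceeds any absolute 0.01.  A decrease beyond slack on three consecutive
iterations aborts the fit with its trace attached.

The reported marginal log likelihood (and hence the iBIC) comes from the
Monte-Carlo estimator at the converged prior: per subject, the log of the
mean data likelihood over parameter draws from the prior (log-sum-exp;
1000 draws by default), summed over subjects — read this way because a sum
of per-subject averaged raw likelihoods would not be a log marginal
likelihood.  iBIC = −2·LML + 2k·ln(N_obs) with k free parameters (each
contributing a mean and a variance hyperparameter) and N_obs the total
choice count.  This bookkeeping is the unique convention consistent with
the reported model-comparison values it is checked against.

Cohorts of one subject are accepted: empirical Bayes then degenerates
gracefully (mean ← mode, variance ← posterior curvature), which is what
per-dataset model recovery needs.

## Synthetic populations and traits

`default_population` is the dispersed world used for parameter recovery:
raw means −0.5 (α slots, natural ≈ 0.38), 0.7 (β, ≈ 2 before the shift),
0.0 (κ, ≈ 1), raw SDs 1.0, and the natural-scale β shifted by +1 in
recovery protocols so that near-random agents — which no model can fit —
are rare.  `separated_population` is the model-recovery world: α_P centred
on 0.62 and α_N on 0.18, κ on 2.2, raw SDs 0.5.  The distinction matters:
a population centred on α_P = α_N (or κ = 1) generates many agents whose
data genuinely belong to the nested simpler model, so a confusion matrix
under the dispersed world is *expected* to leak into nested neighbours;
model identifiability is only a fair question under separation.

Trait scores (primary/secondary psychopathy, trait anxiety) are Gaussian
with questionnaire-realistic means/SDs (≈ 34.4 ± 5.4, 21.0 ± 3.7,
49.1 ± 11.1).  Requested trait → parameter effects are imprinted by
regenerating the targeted parameter as a standardized linear (plus
product-interaction) function of the standardized traits with residual
variance 1 − Σslope² (floored at 0.05), then mapped back to the
parameter's original location and scale.  The generator emulates
*between-subject structure only*: no item-level noise, no scale bounds, no
trait–trait correlations unless imprinted.  A green regression test
therefore establishes that the statistical procedure recovers known
population structure — not that any real trait relation holds.

## Behavioral indices

Advantageous-choice proportions are computed per subject × domain ×
trial type × half, where the five advantageous trial types are 0v10, 0vR,
0v20, 10v20, Rv20 (better option = higher expected coded value), {Z1, Z2}
has no better option, and {R, T10} is scored separately as the
risky-choice proportion.  Halves split each block at trial 105 by
presentation order.  Empty cells are reported as NaN, never as 0.  The
reflection effect is the loss-domain minus gain-domain risky proportion;
the learning-rate contrast is (α_P − α_N)/(α_P + α_N).

A known generative property: a fully symmetric agent (α_P = α_N, κ = 1)
probes the risky option slightly *below* 50% (≈ 0.44 at α = 0.3, β = 2)
because choice-contingent sampling freezes pessimistic risky-value
estimates — the hot-stove effect.  Tests assert an asymmetric band around
0.5 rather than pretending the bias away.

Regressions are standardized (z-scored outcome and predictors), so
coefficients are comparable across predictors.  The moderated regression
enters centered main effects at step 1 and all pairwise products at
step 2, tests the R² change by its F test, and probes significant
interactions by re-fitting with the moderator recoded at ±1 SD; the ±1 SD
slopes equal the closed form b_main ± b_interaction, which is tested
exactly.  The trait screen reports raw and Bonferroni-corrected p values
over the whole trait × parameter grid; the focused re-test of a single
interaction (correcting over the 3 interaction terms only) is left to the
caller, since the appropriate correction family is a judgment call.

## Numerical choices

* Likelihood replay is a compiled (numba) kernel over an 8-entry flat
  parameter layout (α_P, α_N, β, κ × two domains); unsplit parameters
  repeat across domains, absent κ is 1.  Softmax terms use a max-shifted
  log-sum-exp, stable to |βQ| ≈ 700.
* Monte-Carlo marginal likelihoods use log-sum-exp; the estimator was
  checked against 10⁴-point grid quadrature on a one-parameter toy model
  and against the exact N·log ½ closed form at β = 0.
* All randomness flows through named `SeedSequence` substreams of one
  master seed; derived integer seeds stay below 2³¹.
* Overflowing exp transforms during optimizer line searches are allowed to
  produce inf (an infinite temperature yields −inf log likelihood and the
  step is rejected) rather than being clipped.

## Scaling defaults

Full-scale protocols (100 simulated subjects for parameter recovery;
hierarchical fits with 1000 Monte-Carlo draws) run in minutes on one CPU
thanks to the compiled kernel, and are the defaults for the recovery
entry points.  The pipeline command and unit tests use scaled-down
settings (fewer subjects/datasets, 300 draws, capped EM iterations) noted
inline; these change precision, not procedure.

## Known limitations

* The E-step is multi-start local optimization, not a global optimizer;
  pathological multimodal posteriors could return a secondary mode.
* The Laplace M-step assumes roughly Gaussian subject posteriors; with
  very few trials per subject the variance update inherits curvature
  error.
* Population priors are independent per parameter (diagonal covariance),
  so correlated individual differences are not modeled.
* Real-data quantities that depend on the original participants (risky
  proportions, trait correlations) are procedure-tested on synthetic
  cohorts only; nothing here certifies the empirical effect sizes.
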