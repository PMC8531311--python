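# riskrl

Reinforcement learning of risk preference in gain and loss domains:
simulation, hierarchical model fitting, model comparison, recovery studies,
and behavioral analysis for a two-block experience-based learning task.

## The scientific problem

How do people *learn* to like or avoid risk?  In a task where every option's
payoff distribution must be discovered by trial and error, two distinct
learning mechanisms can produce risk preferences:

* **nonlinear subjective utility** — a weight κ on the large outcome, so a
  ±20 payoff enters learning as ±2κ (in coded units of 10); κ < 1 makes the
  50/50 "0 or 20" risky option subjectively worse than a sure 10 in the gain
  domain but better than a sure −10 in the loss domain (the reflection
  effect of prospect theory);
* **asymmetric learning rates** — separate step sizes α_P and α_N for
  positive and negative prediction errors; α_P > α_N over-weights the risky
  option's good outcomes and promotes risk seeking in both domains.

The package implements a family of Rescorla–Wagner models that cross these
mechanisms.  Action values update as

    Q_{t+1}(i) = Q_t(i) + α δ_t,        δ_t = r_t − Q_t(i)

with r_t the subjective outcome (0, ±1, or ±2κ) and α chosen by the sign of
δ_t (and, in domain-split variants, by the gain/loss domain).  Choices
follow a softmax over the two presented options with inverse temperature β:

    p_t(i) = exp(β Q_t(i)) / Σ_i' exp(β Q_t(i'))

Eight variants are registered, from the 2-parameter standard model to the
fully domain-split 8-parameter hybrid (`riskrl models` lists them).

Subject-level parameters get Gaussian population priors on an unbounded
scale (sigmoid for α, exponential for β and κ).  Hyperparameters are
estimated by type-II maximum likelihood: an EM loop alternating per-subject
MAP estimation with Laplace-approximate hyperparameter updates.  Models are
compared by the integrated BIC,

    iBIC = −2 LML + 2k ln(N_obs)

where LML is the Monte-Carlo marginal log likelihood (1000 parameter draws
per subject from the fitted prior) and each of the k free parameters
contributes two hyperparameters (mean, variance) to the penalty.

## The task

Two 210-trial blocks (gain, loss), five options per block: two sure-zero
stimuli, a sure ±10, a sure ±20, and a risky option paying 0 or ±20 with
probability 0.5.  Every unordered pair appears 20 times except the
risk-preference probe {risky, sure 10}, which appears 30 times.  Outcomes
are coded in units of 10.

## Worked example

```python
from riskrl import (default_population, em_fit, get_model, sample_population)

model = get_model("hybrid")
pop = default_population(model, n_subjects=20, beta_shift=1.0)
cohort = [data for _, data in sample_population(pop, seed=11)]
fit = em_fit(cohort, model, seed=0, mc_samples=500)
print(f"iBIC {fit.ibic:.1f}  -LML {-fit.lml:.1f}  "
      f"EM iterations {len(fit.em_trace)}")
print(fit.map_table().head(3).round(3))
```

prints (seed 11):

```
iBIC 6405.7  -LML 3166.7  EM iterations 5
  subject  alpha_p  alpha_n   beta  kappa
0  sim000    0.442    0.448  3.580  0.179
1  sim001    0.551    0.223  5.183  3.217
2  sim002    0.291    0.567  9.893  1.886
```

i.e. a 20-subject simulated cohort fitted in a few seconds: the iBIC is the
model-comparison score (smaller is better), and each row gives one
subject's MAP learning rates, inverse temperature, and utility weight on
the natural scale.

The same flow is available from the shell:

```sh
riskrl simulate --model hybrid_full --n-subjects 51 --seed 42 --out data/
riskrl fit --model hybrid --data data/choices.csv --seed 7 --out fits/
riskrl compare --data data/choices.csv --models all --out ranking.csv
riskrl recover --mode parameter --n 100 --seed 11 --out recovery/
riskrl all --seed 1 --out runs/demo       # end-to-end with a manifest
```

## Acceptance script

`python scripts/acceptance.py --seed 1 --out results/acceptance.json`
recomputes, from scratch: the integrated-BIC values implied by three
reported marginal log likelihoods under this package's penalty convention,
and the minimum true-vs-recovered parameter correlation from a full
100-subject parameter-recovery study of the domain-split hybrid model
(simulation, hierarchical fitting, and correlation all run end to end;
roughly two minutes on one CPU).
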