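# rlcapture

Hierarchical Bayesian Q-learning and value-driven attentional capture, as a
tested, fully synthetic analysis pipeline.

## The scientific problem

When people learn which stimuli pay off, stimulus features that predicted
reward later capture attention automatically, even when they have become
task-irrelevant ("value-driven attentional capture"). This package
implements the analysis chain used to ask *who* develops such capture: it
models trial-by-trial choices in a probabilistic selection task with a
Q-learning model that learns at different rates from high- and low-value
outcomes, estimates those learning rates hierarchically, and relates them to
the reaction-time cost of reward-colored distractors in a visual-search
(capture) task.

Because the original behavioral data are not publicly deposited, the package
ships a first-class synthetic-data generator that emulates the study design
— 20 subjects, 300 learning trials (pairs AB/CD/EF rewarded 80:20, 70:30,
60:40) and 120 search trials per subject (half without a distractor, the
rest split between the high- and low-value colors) — with a configurable,
planted coupling between each synthetic subject's high-reward learning rate
and their distractor slowing, so every downstream statistic is testable end
to end.

## The model

Each stimulus *i* carries an expected value Q_i, updated only when chosen:

    Q_i(t+1) = Q_i(t) + α_High [r(t) − Q_i(t)]   if r = 1 (high reward)
    Q_i(t+1) = Q_i(t) + α_Low  [r(t) − Q_i(t)]   if r = 0 (low reward)

with choices between the two presented stimuli following a softmax with
inverse temperature β:

    P(A) = exp(β Q_A) / (exp(β Q_A) + exp(β Q_B)),   0 ≤ β ≤ 100.

A single-rate control model (one shared α) is fit for model comparison by
group and individual BIC. Estimation is hierarchical: each subject's
parameters are probit-transformed to an unbounded scale z′ (α = Φ(z′),
β = 100·Φ(z′)) and drawn from group-level normals with means μ_z′ ~ N(0, 1)
and SDs δ_z′ ~ U(1, 1.5). The posterior is sampled with an adaptive
Metropolis-within-Gibbs sampler (componentwise and covariance-adapted joint
random-walk moves on z′, conjugate Gibbs for μ_z′, grid inverse-CDF draws
for δ_z′), monitored with split-chain R̂, and summarized by KDE posterior
modes on the natural scale. Capture statistics cover chance-level exclusion,
condition RT means over correct trials, one-way repeated-measures ANOVA with
a linear value trend, Bonferroni-corrected pairwise t-tests, and Spearman /
partial Spearman correlations between learning rates and slowing scores.

## Worked example

The numbered scripts under `analysis/` run the study in order (equivalently:
`rlcapture all --seed 0 --out results/study`):

```bash
python analysis/01_simulate_tasks.py --seed 0 --out results/study
python analysis/02_fit_models.py     --seed 0 --out results/study
python analysis/03_model_selection.py --seed 0 --out results/study
python analysis/04_capture_analysis.py --seed 0 --out results/study
```

At seed 0 this prints (abridged):

```
simulated 20 subjects
  P(choose A|AB) = 0.718
  P(choose C|CD) = 0.720
  P(choose E|EF) = 0.712
  capture mean RT (ms): none=653, low=672, high=751
...
scope=all: group BIC 2a=4281 1a=4679 -> preferred: model_2a
posterior-predictive P(A|AB) by block (simulated vs observed):
  block 1: sim 0.685 obs 0.718
  ...
  block 5: sim 0.801 obs 0.762
distractor-condition ANOVA: F(2, 32) = 16.20, p = 0.0000, partial eta^2 = 0.50
linear value trend: F(1, 16) = 20.44, p = 0.0003
partial Spearman, high-value slowing vs alpha_high (controlling alpha_low):
  rho_pcor = 0.50, p = 0.04624
```

Reading this output: subjects learn all three pairs above chance; the
dual-rate model is preferred over the single-rate control on all-pairs fits;
simulated learning curves track the observed ones; distractor value slows
search RT linearly; and — the headline relationship — subjects with higher
fitted α_High show more slowing from the high-value distractor, detected
here through the full generate → fit → correlate chain (three chance-level
performers were excluded, hence df 32/16).

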