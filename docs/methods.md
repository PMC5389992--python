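# Methods

## Generative model of the tasks

**Learning task.** Three stimulus pairs (AB, CD, EF) are presented for 100
trials each, interleaved in five 60-trial blocks containing 20 trials of
every pair in uniformly shuffled order (the within-block order of the
original task is not specified beyond equal counts, so a uniform shuffle is
used; with a trial count not divisible by five the whole session is shuffled
as one block). Choosing a stimulus pays the high reward (r = 1) with that
stimulus's scheduled probability — A: 0.8, B: 0.2, C: 0.7, D: 0.3, E: 0.6,
F: 0.4 — and the low reward (r = 0) otherwise. The reward magnitudes behind
the binary code (+0.10 / +0.01 points) play no computational role. Choices
are generated by the same Q-learning forward model the likelihood assumes
(softmax over the current Q values of the two presented stimuli; only the
chosen stimulus is updated). Response omissions ("too slow" trials) are
supported — omitted trials carry no choice or reward and are skipped by the
likelihood — but default to probability 0 because no omission rates are
reported for the original task.

**Subjects.** Subject-level parameters live on the probit scale,
z′ = (z′_αHigh, z′_αLow, z′_β), with natural scales α = Φ(z′) and
β = 100·Φ(z′). Synthetic subjects are drawn from group normals whose means
default to the probit-inverse of the AB-restricted reference modes
(α_High = 0.12, α_Low = 0.11, β = 4.65) with between-subject SD 1.0 per
dimension. The SD default deliberately sits inside the fitted model's own
group-SD support (U(1, 1.5)): it produces the wide, realistic individual
differences the correlation analyses need. Recovery experiments override it
(see below).

**Capture task.** 120 search trials per subject: 60 without a distractor,
30 with the high-value color and 30 with the low-value color (largest-
remainder rounding for other fractions). A no-distractor reaction time is
Normal(650 ms, 100 ms); the high-value condition adds 400 ms × α_High and
the low-value condition 100 ms × α_Low; RTs are truncated below at 1 ms and
trials are correct with probability 0.9. This linear coupling is a
deliberately simple stand-in — its only contract is that the planted
learning-rate/slowing relationship is recoverable by the downstream
statistics. The defaults were chosen once as plausible for a pop-out search
task (mean RT ≈ 650–750 ms, ≈ 0.90 accuracy, slowing of tens of
milliseconds) and give the planted α_High–slowing rank correlation ≈ 0.8–0.95
before estimation noise.

What the generator does *not* emulate: real RT distributions are
right-skewed and autocorrelated, error rates vary by condition, subjects
drift and lapse, and real learning-rate/capture coupling is surely not
linear in α. Passing tests therefore demonstrate that the pipeline recovers
relationships of the assumed form at realistic signal-to-noise — not that
the original study's effect sizes would replicate.

## Likelihood and estimation

The trial-sequence log-likelihood walks each subject's trials in order,
accumulating log softmax probabilities (floored at 1e-12) and applying the
delta-rule update with α_High after high rewards and α_Low after low rewards
(a single shared rate in the control model). Q values initialize at 0.5, the
midpoint of the {0,1} reward code, making the first choice of every pair
unbiased; initialization is otherwise unconstrained by the design. In
AB-restricted fits, CD/EF trials are dropped entirely — they share no
stimuli with AB, so they cannot influence AB values. The kernel is compiled
with numba; an independent pure-Python trial walker in the test suite checks
it to 1e-10.

Priors follow the hierarchical specification exactly: μ_z′ ~ N(0, 1),
δ_z′ ~ U(1, 1.5), z′_i ~ N(μ_z′, δ_z′). The U(1, 1.5) group-SD support is
unusually narrow-and-wide at once — it *forbids* group SDs below 1 — and is
implemented verbatim (it is config-overridable via `PriorSpec`); its
consequences are discussed under identifiability.

**Sampler.** Posterior draws come from an adaptive Metropolis-within-Gibbs
scheme targeting the exact log posterior:

- per subject, componentwise Gaussian random-walk Metropolis on each z′
  dimension, with per-subject-per-dimension scales adapted during warmup
  toward ~35% acceptance;
- per subject, a joint random-walk move along a covariance estimated from
  warmup history (classic 2.38²/d scaling) — this follows the strong
  (α_High, β) posterior correlation;
- per subject, an independence proposal from the current group prior
  N(μ_z′, δ_z′), which lets a subject jump between distant regions of a
  nearly flat likelihood ridge;
- conjugate Gibbs draws for each μ_z′;
- inverse-CDF draws for each δ_z′ on a 512-cell grid over [1, 1.5]
  (discretization error ≈ 1e-3, far below MCMC error).

All adaptation stops at the end of warmup, so kept draws leave the posterior
invariant. Each kept draw is separated by `thin` full update sweeps
(default 5; the recovery experiments use 10), and warmup iterations are
thinned identically. Chains are seeded independently from a master seed;
identical seeds reproduce byte-identical draws. Convergence is summarized by
split-chain R̂ for every parameter with a 1.05 convergence flag
(operationalizing "close to 1"). Initialization: z′ ~ N(0, 0.1), δ_z′ at the
support midpoint 1.25.

The sampler was validated in two independent ways during development: with
an empty likelihood it reproduces the prior (μ moments, δ uniformity), and
on a small two-subject problem its posterior means agree with a large
prior-importance-sampling estimate within Monte Carlo error.

**Point estimates.** "Posterior mode" means the maximum of a Gaussian KDE
(normal-reference bandwidth) evaluated on a 512-point grid over the pooled
natural-scale draws; constant samples short-circuit to that constant. Two
group-level summaries are reported per parameter. The primary one is the
KDE mode of the posterior of the *subject average*, mean_i Φ(z′_i) (×100
for β): with a nonlinear link, Φ(μ_z′) is the median subject's parameter
rather than the group mean of parameters, and the subject average is the
quantity whose uncertainty matches the scale on which group estimates of
this model are conventionally tabulated. The transformed group location
Φ(μ_z′) is reported alongside under `<param>_location`. Subject-level point
estimates (used for BIC and the correlation battery) are KDE modes of each
subject's own natural-scale draws.

## Identifiability at this design size — a deliberate finding

With 100 trials of a single 80:20 pair, the dual-rate model's likelihood has
a long, nearly flat ridge trading α_High against β: halving α_High and
raising β fits a realized choice sequence almost as well (≈ 0.3 nats), with
more ridge volume on the low-α/high-β side. The expected log-likelihood
(checked by simulation) peaks at the generating values, so this is a
small-sample geometry problem, not a model error. The forced-wide group SD
prior U(1, 1.5) amplifies it: when data are generated with a small
between-subject spread (probit SD 0.1), the model must spread subjects ~10×
wider than truth, and they spread along the ridge. Consequences, measured
across 10 replicate recovery experiments at the reference modes (20
subjects, 100 AB trials, 2 chains × 500 kept, max R̂ ≈ 1.02):

- the group **α_High** subject-average mode recovers the generating 0.12
  in most replicates (range 0.088–0.225) — the spread is posterior
  variability across generated datasets, not sampler noise;
- **α_Low** recovers well (0.076–0.136 around 0.11);
- **β** is systematically over-estimated (modes ≈ 7–14 against a generating
  4.65) under every summary considered; at this design size the inverse
  temperature is not recoverable under the verbatim priors. A control
  experiment with a group-SD prior admitting small spreads (U(0.05, 1.5))
  largely removes the bias, locating its source in the prior-likelihood
  interaction rather than the sampler or the data volume alone.

The package reports these quantities as computed; the β discrepancy is a
property of the printed model at these study conditions and is documented
rather than patched.

Forward simulation shows a related, smaller effect: simulating a homogeneous
group exactly at the dual-rate point modes slightly overshoots observed
choose-better rates for the asymmetric-rate all-pairs modes (CD ≈ 0.81
simulated), because point-mode simulation omits the subject heterogeneity
present in real group means.

## Statistics

Capture RT means use correct trials only, with no RT trimming (neither rule
is stated for the original task; both are overridable). Chance-level
exclusion uses a one-sided exact binomial test of each subject's pooled
choose-better rate against 0.5 at α = 0.05. The repeated-measures ANOVA is
the classical sums-of-squares partition (no sphericity correction, matching
the uncorrected df convention), with partial η² = SS_cond/(SS_cond +
SS_resid); the linear value trend uses the (−1, 0, +1) contrast over
none < low < high with a one-sample F on (1, n−1) df, reporting F = ∞, p = 0
in the degenerate noise-free case. The Bonferroni family is the three
pairwise condition tests. Spearman correlations use average ranks;
the partial Spearman is the first-order partial Pearson correlation on
ranks with a two-sided t approximation on n − 3 df. All correlation
p-values are two-sided. The correlation battery mirrors the study's:
(1) slowing_high vs α_High partialling α_Low, (2) slowing_low vs α_High,
(3) slowing_diff vs α_High − α_Low, (4) controls — slowing_high vs AB
accuracy and vs the final Q value of A, (5) a leave-one-out repeat of (3)
dropping the lowest α-difference subject.

Model comparison evaluates each subject's likelihood at their natural-scale
posterior modes (a point-estimate surrogate for a maximized likelihood,
since BIC needs one): individual BIC uses that subject's included trial
count with k = 3 (dual-rate) or 2 (single-rate); group BIC uses summed
log-likelihoods, total trials and summed k. The random-effects exceedance
machinery sometimes layered on such comparisons is out of scope.
Posterior-predictive learning curves simulate each subject at their modal
parameters and bin AB trials into five 20-trial blocks, matching the
five-block task structure.

## Problem sizes and numerical choices

Default analysis runs use 20 subjects, 300 learning trials and 120 capture
trials each, 4 chains × 1000 warmup/1000 kept (thin 5); the full pipeline
completes in a few minutes on one CPU. Test-suite experiments use the same
study conditions with 2-chain samplers and 300–500 kept draws, sizes chosen
as the smallest at which the monitored quantities stabilize. Probabilities
are floored at 1e-12 before logs; softmax differences are computed in
overflow-safe form; KDE modes fall back to the sample value for degenerate
constant draws.

## Known limitations

- The capture-task generative model is linear in the learning rates with
  homoskedastic Gaussian RT noise; it is a recoverability harness, not a
  cognitive model of visual search.
- β is not identifiable at 100 single-pair trials under the verbatim priors
  (see above); conclusions about β from fits of this design should rely on
  sensitivity analyses over the group-SD prior.
- The BIC uses point-estimate likelihoods, inheriting their ridge bias;
  comparisons are only trusted for the direction of preference, which is
  what the tests assert.
- No variational approximation and no alternative link functions are
  provided.
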