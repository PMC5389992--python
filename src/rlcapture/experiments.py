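"""Canned study-condition experiments: forward-simulation fidelity and
hierarchical parameter recovery.

These are the desk-scale experiments the synthetic pipeline is built around:
the generator plays the role of the study participants, with group-level
parameters set to the reference fit modes the generator emulates
(AB-restricted fit: alpha_high 0.12, alpha_low 0.11, beta 4.65; all-pairs
fit: alpha_high 0.18, alpha_low 0.08, beta 4.95).
"""
from __future__ import annotations

import numpy as np
from scipy.special import ndtri

from .hierarchical import GroupPosterior, PriorSpec, run_sampler
from .qlearning import ModelSpec, SubjectParams
from .synthetic import draw_subject_params, simulate_learning_task
from .task import TaskDesign

AB_FIT_MODES = SubjectParams(alpha_high=0.12, alpha_low=0.11, beta=4.65)
ALL_FIT_MODES = SubjectParams(alpha_high=0.18, alpha_low=0.08, beta=4.95)


def ab_only_design(trials_per_pair: int = 100) -> TaskDesign:
    return TaskDesign(
        pairs=("AB",), high_reward_prob={"AB": 0.8}, trials_per_pair=trials_per_pair
    )


def forward_choice_rate(
    params: SubjectParams,
    pair: str,
    seed: int,
    n_subjects: int = 20,
    n_replicates: int = 20,
) -> float:
    """Mean choose-better rate for one pair, simulating a homogeneous group
    at the given parameters, averaged over replicate seeds."""
    design = TaskDesign()
    better = pair[0]
    child = np.random.SeedSequence(seed).spawn(n_replicates)
    rates = []
    for ss in child:
        trials = simulate_learning_task(
            [params] * n_subjects, design, np.random.default_rng(ss)
        )
        sub = trials[trials["pair"] == pair]
        rates.append(float((sub["chosen"] == better).mean()))
    return float(np.mean(rates))


def recovery_experiment(
    seed: int,
    n_subjects: int = 20,
    trials_per_pair: int = 100,
    between_subject_sd: float = 0.1,
    n_chains: int = 2,
    n_warmup: int = 500,
    n_samples: int = 500,
    thin: int = 10,
) -> GroupPosterior:
    """Generate-and-refit experiment at the AB-fit reference modes.

    Subjects' probit-scale parameters are drawn around the group means
    implied by the AB-fit modes with a small between-subject SD; choices are
    simulated on the 80:20 pair and the dual-rate hierarchical model is
    refit by MCMC. The returned posterior carries the group-level
    natural-scale KDE modes used to judge recovery.
    """
    means = (
        ndtri(AB_FIT_MODES.alpha_high),
        ndtri(AB_FIT_MODES.alpha_low),
        ndtri(AB_FIT_MODES.beta / 100.0),
    )
    ss = np.random.SeedSequence(seed).spawn(3)
    params = draw_subject_params(
        means,
        (between_subject_sd,) * 3,
        n_subjects,
        np.random.default_rng(ss[0]),
    )
    design = ab_only_design(trials_per_pair)
    data = simulate_learning_task(params, design, np.random.default_rng(ss[1]))
    spec = ModelSpec(n_learning_rates=2, q_init=0.5, fit_scope="AB_only")
    return run_sampler(
        data,
        PriorSpec(),
        spec,
        n_chains=n_chains,
        n_warmup=n_warmup,
        n_samples=n_samples,
        seed=int(ss[2].generate_state(1)[0] % (2**31)),
        thin=thin,
    )
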