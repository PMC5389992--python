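"""Q-learning computational kernel: value update, softmax choice, likelihood.

The model maintains an expected value Q for each stimulus. After choosing
stimulus *i* and receiving a binary reward r, only the chosen stimulus is
updated,

    Q_i(t+1) = Q_i(t) + alpha * (r - Q_i(t)),

with alpha = alpha_high after a high reward (r = 1) and alpha = alpha_low
after a low reward (r = 0); the one-learning-rate control model shares a
single alpha for both outcomes. Choices between the two presented stimuli
follow a softmax with inverse temperature beta,

    P(first) = exp(beta*Q_first) / (exp(beta*Q_first) + exp(beta*Q_second)).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy.special import expit, ndtr, ndtri

from . import _kernels
from .task import PAIR_STIMULI, STIM_INDEX, STIMULI, TaskDesign

BETA_SCALE = 100.0

LEARNING_COLUMNS = [
    "subject_id", "trial_index", "pair", "chosen", "unchosen", "reward", "omitted",
]


def probit_to_natural(z: np.ndarray) -> tuple[float, float, float]:
    """Map probit-scale (z_alpha_high, z_alpha_low, z_beta) to natural scale."""
    z = np.asarray(z, dtype=float)
    return float(ndtr(z[0])), float(ndtr(z[1])), float(BETA_SCALE * ndtr(z[2]))


@dataclass(frozen=True)
class SubjectParams:
    """One subject's Q-learning parameters on the natural scale.

    ``z_probit`` holds the unbounded probit-scale counterparts
    (z such that alpha = Phi(z), beta = 100*Phi(z)); when provided, the
    natural-scale fields must match the link to 1e-10.
    """

    alpha_high: float
    alpha_low: float
    beta: float
    z_probit: tuple[float, float, float] | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha_high <= 1.0:
            raise ValueError(f"alpha_high out of [0, 1]: {self.alpha_high}")
        if not 0.0 <= self.alpha_low <= 1.0:
            raise ValueError(f"alpha_low out of [0, 1]: {self.alpha_low}")
        if not 0.0 <= self.beta <= BETA_SCALE:
            raise ValueError(f"beta out of [0, 100]: {self.beta}")
        if self.z_probit is not None:
            ah, al, b = probit_to_natural(np.asarray(self.z_probit))
            if (
                abs(ah - self.alpha_high) > 1e-10
                or abs(al - self.alpha_low) > 1e-10
                or abs(b - self.beta) > 1e-10
            ):
                raise ValueError("natural-scale fields do not match z_probit link")

    @classmethod
    def from_probit(cls, z: np.ndarray | tuple[float, float, float]) -> "SubjectParams":
        z = tuple(float(v) for v in np.asarray(z, dtype=float))
        ah, al, b = probit_to_natural(np.asarray(z))
        return cls(alpha_high=ah, alpha_low=al, beta=b, z_probit=z)

    @classmethod
    def from_natural(
        cls, alpha_high: float, alpha_low: float, beta: float
    ) -> "SubjectParams":
        z = (
            float(ndtri(alpha_high)),
            float(ndtri(alpha_low)),
            float(ndtri(beta / BETA_SCALE)),
        )
        if np.all(np.isfinite(z)):
            return cls(alpha_high, alpha_low, beta, z_probit=z)
        return cls(alpha_high, alpha_low, beta)


@dataclass(frozen=True)
class ModelSpec:
    """Which Q-model variant is being fit.

    n_learning_rates=2 is the dual-rate model; 1 shares a single learning
    rate across outcomes. fit_scope selects whether the likelihood uses all
    pairs or only AB trials (non-AB trials share no stimuli with AB, so in
    AB-only scope they are dropped entirely).
    """

    n_learning_rates: int = 2
    q_init: float = 0.5
    fit_scope: str = "all_pairs"

    def __post_init__(self) -> None:
        if self.n_learning_rates not in (1, 2):
            raise ValueError("n_learning_rates must be 1 or 2")
        if not 0.0 <= self.q_init <= 1.0:
            raise ValueError("q_init must lie in [0, 1]")
        if self.fit_scope not in ("AB_only", "all_pairs"):
            raise ValueError("fit_scope must be 'AB_only' or 'all_pairs'")

    @property
    def n_params(self) -> int:
        """Subject-level parameter count (learning rates + beta)."""
        return self.n_learning_rates + 1


class QUpdate(NamedTuple):
    q: float
    prediction_error: float


def q_update(
    q_chosen: float, reward: int, params: SubjectParams, spec: ModelSpec
) -> QUpdate:
    """Delta-rule update of the chosen stimulus's Q value.

    Returns the new Q and the prediction error r - Q as a by-product. Under
    the one-rate model alpha_high is used for both outcomes (callers
    constructing 1-alpha parameters should set alpha_low = alpha_high).
    """
    if reward not in (0, 1):
        raise ValueError(f"reward must be 0 or 1, got {reward!r}")
    if not 0.0 <= q_chosen <= 1.0:
        raise ValueError(f"q_chosen out of [0, 1]: {q_chosen}")
    delta = reward - q_chosen
    if spec.n_learning_rates == 1:
        alpha = params.alpha_high
    else:
        alpha = params.alpha_high if reward == 1 else params.alpha_low
    return QUpdate(q=q_chosen + alpha * delta, prediction_error=delta)


def choice_prob(q_first: float, q_second: float, beta: float) -> float:
    """Softmax probability of choosing the first of two presented stimuli."""
    if not 0.0 <= beta <= BETA_SCALE:
        raise ValueError(f"beta out of [0, 100]: {beta}")
    return float(expit(beta * (q_first - q_second)))


def _trials_to_arrays(
    trials: pd.DataFrame, spec: ModelSpec
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Encode one subject's trial table as index arrays for the kernel."""
    pair = trials["pair"].to_numpy()
    omitted = trials["omitted"].to_numpy(dtype=bool)
    include = ~omitted
    if spec.fit_scope == "AB_only":
        include &= pair == "AB"
    first = np.array([STIM_INDEX[PAIR_STIMULI[p][0]] for p in pair], dtype=np.int64)
    second = np.array([STIM_INDEX[PAIR_STIMULI[p][1]] for p in pair], dtype=np.int64)
    chosen = np.array(
        [STIM_INDEX.get(c, -1) for c in trials["chosen"]], dtype=np.int64
    )
    reward = (
        trials["reward"].fillna(0).to_numpy(dtype=np.int64)
        if trials["reward"].isna().any()
        else trials["reward"].to_numpy(dtype=np.int64)
    )
    if np.any((chosen < 0) & include):
        raise ValueError("non-omitted trial with unknown chosen stimulus")
    chosen = np.where(chosen < 0, first, chosen)  # placeholder on omitted rows
    return chosen, first, second, reward, include


def _validate_single_subject(trials: pd.DataFrame) -> None:
    if trials["subject_id"].nunique() > 1:
        raise ValueError("sequence_loglik expects trials from a single subject")
    idx = trials["trial_index"].to_numpy()
    if np.any(np.diff(idx) <= 0):
        raise ValueError("trials must be sorted by strictly increasing trial_index")


def sequence_loglik(
    trials: pd.DataFrame, params: SubjectParams, spec: ModelSpec
) -> float:
    """Log-likelihood of one subject's choice sequence under the Q-model.

    Walks the trials in order: the choice probability on each included trial
    comes from the softmax over the presented pair's current Q values; the
    chosen stimulus is then updated. All Q values start at ``spec.q_init``.
    Probabilities are floored at 1e-12 before the log.
    """
    _validate_single_subject(trials)
    chosen, first, second, reward, include = _trials_to_arrays(trials, spec)
    alpha_low = params.alpha_high if spec.n_learning_rates == 1 else params.alpha_low
    out = _kernels.seq_loglik_many(
        chosen[None, :],
        first[None, :],
        second[None, :],
        reward[None, :],
        include[None, :],
        np.array([params.alpha_high]),
        np.array([alpha_low]),
        np.array([params.beta]),
        spec.q_init,
    )
    return float(out[0])


def _block_pair_sequence(
    design: TaskDesign, rng: np.random.Generator
) -> list[str]:
    """Pair presentation order: uniform shuffles within equal-count blocks.

    The task ran five blocks with equal numbers of each pair per block; when
    trials_per_pair is not divisible by 5 a single fully shuffled block is
    used instead.
    """
    n_blocks = 5 if design.trials_per_pair % 5 == 0 else 1
    per_block = design.trials_per_pair // n_blocks
    order: list[str] = []
    for _ in range(n_blocks):
        block = [p for p in design.pairs for _ in range(per_block)]
        rng.shuffle(block)
        order.extend(block)
    return order


def simulate_agent_choices(
    params: SubjectParams,
    design: TaskDesign,
    spec: ModelSpec,
    seed: int | np.random.Generator,
    subject_id: str = "s01",
) -> pd.DataFrame:
    """Forward-generative twin of `sequence_loglik` for a single agent.

    Rewards are Bernoulli draws from each stimulus's schedule (e.g. A pays
    the high reward with probability 0.8, B with 0.2). This is the single
    code path behind `synthetic.simulate_learning_task`.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    pair_order = _block_pair_sequence(design, rng)
    T = len(pair_order)
    first = np.array(
        [STIM_INDEX[PAIR_STIMULI[p][0]] for p in pair_order], dtype=np.int64
    )
    second = np.array(
        [STIM_INDEX[PAIR_STIMULI[p][1]] for p in pair_order], dtype=np.int64
    )
    p_high = np.zeros(6)
    for pr in design.pairs:
        a, b = PAIR_STIMULI[pr]
        p_high[STIM_INDEX[a]] = design.reward_prob(a)
        p_high[STIM_INDEX[b]] = design.reward_prob(b)
    alpha_low = params.alpha_high if spec.n_learning_rates == 1 else params.alpha_low
    chosen, reward = _kernels.simulate_choices(
        first,
        second,
        p_high,
        params.alpha_high,
        alpha_low,
        params.beta,
        spec.q_init,
        rng.random(T),
        rng.random(T),
    )
    omitted = (
        rng.random(T) < design.omission_rate
        if design.omission_rate > 0
        else np.zeros(T, dtype=bool)
    )
    rows = pd.DataFrame(
        {
            "subject_id": subject_id,
            "trial_index": np.arange(1, T + 1),
            "pair": pair_order,
            "chosen": [STIMULI[c] for c in chosen],
            "unchosen": [
                STIMULI[second[t]] if chosen[t] == first[t] else STIMULI[first[t]]
                for t in range(T)
            ],
            "reward": reward,
            "omitted": omitted,
        }
    )
    # omitted trials carry no choice or reward
    rows.loc[omitted, ["chosen", "unchosen"]] = ""
    rows.loc[omitted, "reward"] = 0
    return rows[LEARNING_COLUMNS]


def final_q(
    trials: pd.DataFrame, params: SubjectParams, spec: ModelSpec
) -> dict[str, float]:
    """Q values for all stimuli at the end of one subject's learning data."""
    _validate_single_subject(trials)
    chosen, _, _, reward, include = _trials_to_arrays(trials, spec)
    alpha_low = params.alpha_high if spec.n_learning_rates == 1 else params.alpha_low
    q = _kernels.final_q_values(
        chosen, reward, include, params.alpha_high, alpha_low, spec.q_init
    )
    return {s: float(q[i]) for s, i in STIM_INDEX.items()}
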