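"""Task structure for the probabilistic selection and attentional capture tasks.

The learning task presents three fixed color pairs (AB, CD, EF). Within each
pair the first stimulus is the "better" option: choosing it yields a high
reward (r = 1) with the pair's scheduled probability, while the second
stimulus yields a high reward with the complementary probability. The capture
task is a visual search with a shape-singleton target; on a subset of trials a
distractor carries the color previously associated with high (A) or low (B)
reward.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

STIMULI = ("A", "B", "C", "D", "E", "F")
STIM_INDEX = {s: i for i, s in enumerate(STIMULI)}
PAIR_STIMULI = {"AB": ("A", "B"), "CD": ("C", "D"), "EF": ("E", "F")}

CAPTURE_CONDITIONS = ("none", "high", "low")

DEFAULT_HIGH_REWARD_PROB = {"AB": 0.80, "CD": 0.70, "EF": 0.60}


@dataclass(frozen=True)
class TaskDesign:
    """Design of one synthetic session (learning + capture task).

    Parameters
    ----------
    pairs
        Ordered pair labels presented in the learning task. Subsets of
        ``("AB", "CD", "EF")`` are allowed (e.g. an AB-only session).
    high_reward_prob
        Probability that choosing the *better* stimulus of each pair yields
        the high reward; the worse stimulus yields it with the complement.
    trials_per_pair
        Learning trials per pair (default 100, i.e. 300 in the full task).
    capture_trials
        Search trials in the capture task (default 120).
    capture_condition_fractions
        Fraction of capture trials per distractor condition; must sum to 1.
    choice_deadline_ms
        Response deadline in the learning task; choices slower than this are
        recorded as omissions.
    omission_rate
        Probability that a learning trial is omitted ("too slow"); 0 by
        default since no omission rates are reported for the original task.
    """

    pairs: tuple[str, ...] = ("AB", "CD", "EF")
    high_reward_prob: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_HIGH_REWARD_PROB)
    )
    trials_per_pair: int = 100
    capture_trials: int = 120
    capture_condition_fractions: dict[str, float] = field(
        default_factory=lambda: {"none": 0.5, "high": 0.25, "low": 0.25}
    )
    choice_deadline_ms: float = 1250.0
    omission_rate: float = 0.0

    def __post_init__(self) -> None:
        if not self.pairs:
            raise ValueError("design must include at least one pair")
        for pair in self.pairs:
            if pair not in PAIR_STIMULI:
                raise ValueError(f"unknown pair label {pair!r}")
            p = self.high_reward_prob.get(pair)
            if p is None or not 0.5 < p <= 1.0:
                raise ValueError(
                    f"high_reward_prob[{pair!r}] must lie in (0.5, 1], got {p}"
                )
        if self.trials_per_pair < 1:
            raise ValueError("trials_per_pair must be positive")
        if self.capture_trials < 1:
            raise ValueError("capture_trials must be positive")
        unknown = set(self.capture_condition_fractions) - set(CAPTURE_CONDITIONS)
        if unknown:
            raise ValueError(f"unknown capture conditions {sorted(unknown)}")
        total = sum(self.capture_condition_fractions.values())
        if not math.isclose(total, 1.0, abs_tol=1e-12):
            raise ValueError(f"capture condition fractions sum to {total}, not 1")
        if self.choice_deadline_ms <= 0:
            raise ValueError("choice_deadline_ms must be positive")
        if not 0.0 <= self.omission_rate < 1.0:
            raise ValueError("omission_rate must lie in [0, 1)")

    def reward_prob(self, stimulus: str) -> float:
        """P(high reward | choosing `stimulus`) under the pair schedules."""
        for pair, (better, worse) in PAIR_STIMULI.items():
            if stimulus == better:
                return self.high_reward_prob[pair]
            if stimulus == worse:
                return 1.0 - self.high_reward_prob[pair]
        raise ValueError(f"unknown stimulus {stimulus!r}")

    def capture_condition_counts(self) -> dict[str, int]:
        """Integer trial counts per capture condition (largest-remainder)."""
        raw = {
            c: self.capture_condition_fractions.get(c, 0.0) * self.capture_trials
            for c in CAPTURE_CONDITIONS
        }
        counts = {c: int(math.floor(v)) for c, v in raw.items()}
        short = self.capture_trials - sum(counts.values())
        for c in sorted(raw, key=lambda c: raw[c] - counts[c], reverse=True)[:short]:
            counts[c] += 1
        return counts
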