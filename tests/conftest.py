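import numpy as np
import pandas as pd
import pytest

from rlcapture import ModelSpec, SubjectParams, TaskDesign

TABLE_AB = SubjectParams(alpha_high=0.12, alpha_low=0.11, beta=4.65)
TABLE_ALL = SubjectParams(alpha_high=0.18, alpha_low=0.08, beta=4.95)


@pytest.fixture(scope="session")
def default_design() -> TaskDesign:
    return TaskDesign()


@pytest.fixture(scope="session")
def ab_design() -> TaskDesign:
    """AB-only session: 100 trials of the 80:20 pair."""
    return TaskDesign(
        pairs=("AB",), high_reward_prob={"AB": 0.8}, trials_per_pair=100
    )


@pytest.fixture(scope="session")
def dual_spec() -> ModelSpec:
    return ModelSpec(n_learning_rates=2, q_init=0.5, fit_scope="all_pairs")


def make_learning_table(records) -> pd.DataFrame:
    """Build a learning-trial table from (pair, chosen, reward) tuples."""
    rows = []
    for t, (pair, chosen, reward) in enumerate(records, start=1):
        unchosen = pair[1] if chosen == pair[0] else pair[0]
        rows.append(
            {
                "subject_id": "s01",
                "trial_index": t,
                "pair": pair,
                "chosen": chosen,
                "unchosen": unchosen,
                "reward": reward,
                "omitted": False,
            }
        )
    return pd.DataFrame(rows)


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(20160629)
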