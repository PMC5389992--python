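"""Synthetic behavioral data with the statistical structure the analysis assumes.

Subject-level Q-learning parameters are drawn on the probit scale from
group-level normals and pushed through the probit link, mirroring the
hierarchical generative model. Learning-task choices come from the Q-learning
forward model; capture-task reaction times are generated with a configurable
linear coupling between a subject's learning rates and distractor slowing, so
the correlation analyses downstream have a planted, recoverable signal.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtri

from .qlearning import LEARNING_COLUMNS, ModelSpec, SubjectParams, simulate_agent_choices
from .task import CAPTURE_CONDITIONS, TaskDesign

CAPTURE_COLUMNS = ["subject_id", "trial_index", "condition", "correct", "rt_ms"]

#: Group probit-scale means matching the estimated AB-fit modes
#: (alpha_high 0.12, alpha_low 0.11, beta 4.65).
DEFAULT_GROUP_MEANS_PROBIT = (
    float(ndtri(0.12)),
    float(ndtri(0.11)),
    float(ndtri(0.0465)),
)
DEFAULT_GROUP_SDS_PROBIT = (1.0, 1.0, 1.0)


@dataclass(frozen=True)
class CouplingSpec:
    """Generative link between learning rates and capture-task slowing.

    RT on a no-distractor trial is Normal(baseline_rt_ms, rt_noise_sd_ms);
    high-value-distractor trials add slowing_slope_high * alpha_high ms and
    low-value trials add slowing_slope_low * alpha_low ms. This linear model
    is a stand-in whose only contract is that planted learning-rate/slowing
    relationships are recoverable by the capture statistics.
    """

    baseline_rt_ms: float = 650.0
    slowing_slope_high: float = 400.0
    slowing_slope_low: float = 100.0
    rt_noise_sd_ms: float = 100.0
    error_rate: float = 0.10

    def __post_init__(self) -> None:
        if self.baseline_rt_ms <= 0:
            raise ValueError("baseline_rt_ms must be positive")
        if self.rt_noise_sd_ms <= 0:
            raise ValueError("rt_noise_sd_ms must be positive")
        if not 0.0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")


def draw_subject_params(
    group_means_probit,
    group_sds_probit,
    n_subjects: int,
    seed: int | np.random.Generator,
) -> list[SubjectParams]:
    """Draw subjects' probit-scale parameters from group-level normals."""
    means = np.asarray(group_means_probit, dtype=float)
    sds = np.asarray(group_sds_probit, dtype=float)
    if means.shape != (3,) or sds.shape != (3,):
        raise ValueError("group means and SDs must each have 3 entries")
    if np.any(sds <= 0):
        raise ValueError("group SDs must be strictly positive")
    if n_subjects < 1:
        raise ValueError("n_subjects must be at least 1")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    z = rng.normal(means, sds, size=(n_subjects, 3))
    return [SubjectParams.from_probit(zi) for zi in z]


def subject_ids(n_subjects: int) -> list[str]:
    return [f"s{i + 1:02d}" for i in range(n_subjects)]


def simulate_learning_task(
    params: list[SubjectParams],
    design: TaskDesign,
    seed: int | np.random.Generator,
    spec: ModelSpec | None = None,
) -> pd.DataFrame:
    """Simulate the probabilistic selection task for a group of subjects.

    Each subject runs `trials_per_pair` trials of every pair, interleaved in
    equal-count blocks; choices follow the softmax over current Q values and
    rewards follow each stimulus's schedule. A single shared generator is
    advanced across subjects, so a one-subject call reproduces
    `simulate_agent_choices` with the same seed exactly.
    """
    if not params:
        raise ValueError("at least one subject is required")
    spec = spec or ModelSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    tables = [
        simulate_agent_choices(p, design, spec, rng, subject_id=sid)
        for sid, p in zip(subject_ids(len(params)), params)
    ]
    return pd.concat(tables, ignore_index=True)[LEARNING_COLUMNS]


def simulate_capture_task(
    params: list[SubjectParams],
    design: TaskDesign,
    coupling: CouplingSpec,
    seed: int | np.random.Generator,
) -> pd.DataFrame:
    """Simulate the attentional capture task with planted learning-rate coupling."""
    if not params:
        raise ValueError("at least one subject is required")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    counts = design.capture_condition_counts()
    rows = []
    for sid, p in zip(subject_ids(len(params)), params):
        conditions = np.array(
            [c for c in CAPTURE_CONDITIONS for _ in range(counts[c])], dtype=object
        )
        rng.shuffle(conditions)
        slowing = np.zeros(len(conditions))
        slowing[conditions == "high"] = coupling.slowing_slope_high * p.alpha_high
        slowing[conditions == "low"] = coupling.slowing_slope_low * p.alpha_low
        rt = coupling.baseline_rt_ms + slowing + rng.normal(
            0.0, coupling.rt_noise_sd_ms, size=len(conditions)
        )
        rt = np.maximum(rt, 1.0)
        correct = rng.random(len(conditions)) >= coupling.error_rate
        rows.append(
            pd.DataFrame(
                {
                    "subject_id": sid,
                    "trial_index": np.arange(1, len(conditions) + 1),
                    "condition": conditions,
                    "correct": correct,
                    "rt_ms": rt,
                }
            )
        )
    return pd.concat(rows, ignore_index=True)[CAPTURE_COLUMNS]


def write_learning_csv(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def write_capture_csv(trials: pd.DataFrame, path: str | Path) -> None:
    trials.to_csv(path, index=False)


def read_learning_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=False, na_values=[])
    df["omitted"] = df["omitted"].astype(str).str.lower().isin(["true", "1"])
    df["chosen"] = df["chosen"].astype(str).replace("nan", "")
    df["reward"] = pd.to_numeric(df["reward"], errors="coerce").fillna(0).astype(int)
    df["trial_index"] = df["trial_index"].astype(int)
    return df[LEARNING_COLUMNS]


def read_capture_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    df["correct"] = df["correct"].astype(bool)
    return df[CAPTURE_COLUMNS]


def write_truth_json(params: list[SubjectParams], path: str | Path) -> None:
    """Ground-truth subject parameters, for recovery tests."""
    payload = {
        sid: {
            "alpha_high": p.alpha_high,
            "alpha_low": p.alpha_low,
            "beta": p.beta,
            "z_probit": list(p.z_probit) if p.z_probit is not None else None,
        }
        for sid, p in zip(subject_ids(len(params)), params)
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_truth_json(path: str | Path) -> dict[str, SubjectParams]:
    payload = json.loads(Path(path).read_text())
    return {
        sid: SubjectParams(
            alpha_high=v["alpha_high"],
            alpha_low=v["alpha_low"],
            beta=v["beta"],
            z_probit=tuple(v["z_probit"]) if v.get("z_probit") else None,
        )
        for sid, v in payload.items()
    }
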