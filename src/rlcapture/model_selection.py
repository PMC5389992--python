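"""BIC model comparison (dual-rate vs single-rate) and posterior-predictive
learning curves.

The likelihood entering the BIC is evaluated at each subject's natural-scale
posterior modes (a point-estimate surrogate for the maximized likelihood).
The group BIC uses the summed log-likelihood, total included trial count and
summed subject-level parameter count; the individual BIC uses each subject's
own trial count and parameter count (3 for the dual-rate model, 2 for the
single-rate control).
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .hierarchical import GroupPosterior
from .qlearning import ModelSpec, SubjectParams, sequence_loglik, simulate_agent_choices
from .task import TaskDesign


def bic(loglik: float, k: int, n_obs: int) -> float:
    """Bayesian Information Criterion, -2*loglik + k*ln(n_obs)."""
    if k < 1:
        raise ValueError("k must be at least 1")
    if n_obs < 1:
        raise ValueError("n_obs must be at least 1")
    return -2.0 * float(loglik) + k * float(np.log(n_obs))


def _subject_params_from_modes(fit: GroupPosterior) -> dict[str, SubjectParams]:
    """Natural-scale posterior-mode parameters for every fitted subject."""
    assert fit.subject_modes is not None
    out = {}
    for sid, row in fit.subject_modes.iterrows():
        if fit.spec.n_learning_rates == 2:
            out[sid] = SubjectParams(
                alpha_high=float(row["alpha_high"]),
                alpha_low=float(row["alpha_low"]),
                beta=float(row["beta"]),
            )
        else:
            out[sid] = SubjectParams(
                alpha_high=float(row["alpha"]),
                alpha_low=float(row["alpha"]),
                beta=float(row["beta"]),
            )
    return out


@dataclass
class FitComparison:
    """Group and mean-individual BIC for the 2-rate and 1-rate models."""

    bic_group: dict[str, float]
    bic_individual_mean: dict[str, float]
    loglik_per_subject: pd.DataFrame  # columns: model_2a, model_1a
    k: dict[str, int]
    preferred: str = field(init=False)

    def __post_init__(self) -> None:
        self.preferred = min(self.bic_group, key=self.bic_group.get)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "bic_group": self.bic_group,
            "bic_individual_mean": self.bic_individual_mean,
            "k": self.k,
            "preferred": self.preferred,
            "loglik_per_subject": self.loglik_per_subject.to_dict(orient="index"),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def _per_subject_loglik(
    data: pd.DataFrame, fit: GroupPosterior, spec: ModelSpec
) -> tuple[pd.Series, pd.Series]:
    params = _subject_params_from_modes(fit)
    missing = set(data["subject_id"].unique()) - set(params)
    if missing:
        raise ValueError(f"fit is missing subjects {sorted(missing)}")
    logliks, counts = {}, {}
    for sid, p in params.items():
        sub = data[data["subject_id"] == sid].sort_values("trial_index")
        logliks[sid] = sequence_loglik(sub, p, spec)
        included = ~sub["omitted"].to_numpy(dtype=bool)
        if spec.fit_scope == "AB_only":
            included &= sub["pair"].to_numpy() == "AB"
        counts[sid] = int(included.sum())
    return pd.Series(logliks), pd.Series(counts)


def compare_models(
    data: pd.DataFrame,
    fit_2a: GroupPosterior,
    fit_1a: GroupPosterior,
    spec: ModelSpec,
) -> FitComparison:
    """Compare the dual-rate and single-rate fits on the same data by BIC."""
    if fit_2a.spec.n_learning_rates != 2 or fit_1a.spec.n_learning_rates != 1:
        raise ValueError("fit_2a must be the 2-rate fit and fit_1a the 1-rate fit")
    if sorted(fit_2a.subject_ids) != sorted(fit_1a.subject_ids):
        raise ValueError("fits were not run on the same subjects")
    spec_2a = ModelSpec(2, spec.q_init, spec.fit_scope)
    spec_1a = ModelSpec(1, spec.q_init, spec.fit_scope)
    ll2, n_trials = _per_subject_loglik(data, fit_2a, spec_2a)
    ll1, _ = _per_subject_loglik(data, fit_1a, spec_1a)
    k2, k1 = 3, 2
    n_subj = len(ll2)
    bic_group = {
        "model_2a": bic(float(ll2.sum()), k2 * n_subj, int(n_trials.sum())),
        "model_1a": bic(float(ll1.sum()), k1 * n_subj, int(n_trials.sum())),
    }
    bic_ind = {
        "model_2a": float(
            np.mean([bic(ll2[s], k2, n_trials[s]) for s in ll2.index])
        ),
        "model_1a": float(
            np.mean([bic(ll1[s], k1, n_trials[s]) for s in ll1.index])
        ),
    }
    per_subject = pd.DataFrame({"model_2a": ll2, "model_1a": ll1})
    per_subject.index.name = "subject_id"
    return FitComparison(
        bic_group=bic_group,
        bic_individual_mean=bic_ind,
        loglik_per_subject=per_subject,
        k={"model_2a": k2 * n_subj, "model_1a": k1 * n_subj},
    )


def observed_learning_curve(
    data: pd.DataFrame, pair: str = "AB", block_size: int = 20
) -> pd.DataFrame:
    """Observed P(choose better | pair) per block of `block_size` pair trials."""
    rows = []
    better = pair[0]
    for sid, sub in data.groupby("subject_id"):
        ab = sub[(sub["pair"] == pair) & (~sub["omitted"])].sort_values("trial_index")
        chose_better = (ab["chosen"] == better).to_numpy(dtype=float)
        for b in range(len(chose_better) // block_size):
            rows.append(
                {
                    "subject_id": sid,
                    "block": b + 1,
                    "observed": chose_better[b * block_size : (b + 1) * block_size].mean(),
                }
            )
    return pd.DataFrame(rows)


def posterior_predictive_curves(
    fit: GroupPosterior,
    design: TaskDesign,
    spec: ModelSpec,
    n_reps: int,
    seed: int,
    observed: pd.DataFrame | None = None,
    block_size: int = 20,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Simulate learning curves at each subject's posterior-mode parameters.

    For every fitted subject, `n_reps` task runs are simulated and AB trials
    are binned into blocks of `block_size`; returns a per-subject table
    (`subject_id, block, observed, simulated_mean, simulated_sem`) and a
    group-level table (mean and SEM over subjects per block).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    params = _subject_params_from_modes(fit)
    rng = np.random.default_rng(seed)
    rows = []
    n_blocks = design.trials_per_pair // block_size
    for sid, p in params.items():
        per_rep = np.empty((n_reps, n_blocks))
        for rep in range(n_reps):
            sim = simulate_agent_choices(p, design, spec, rng, subject_id=sid)
            ab = sim[sim["pair"] == "AB"]
            chose_a = (ab["chosen"] == "A").to_numpy(dtype=float)
            for b in range(n_blocks):
                per_rep[rep, b] = chose_a[b * block_size : (b + 1) * block_size].mean()
        for b in range(n_blocks):
            rows.append(
                {
                    "subject_id": sid,
                    "block": b + 1,
                    "simulated_mean": per_rep[:, b].mean(),
                    "simulated_sem": per_rep[:, b].std(ddof=1) / np.sqrt(n_reps)
                    if n_reps > 1
                    else 0.0,
                }
            )
    curves = pd.DataFrame(rows)
    if observed is not None:
        obs = observed_learning_curve(observed, block_size=block_size)
        curves = curves.merge(obs, on=["subject_id", "block"], how="left")
    else:
        curves["observed"] = np.nan
    curves = curves[
        ["subject_id", "block", "observed", "simulated_mean", "simulated_sem"]
    ]
    group = (
        curves.groupby("block")
        .agg(
            observed_mean=("observed", "mean"),
            simulated_mean=("simulated_mean", "mean"),
            simulated_sem=(
                "simulated_mean",
                lambda v: v.std(ddof=1) / np.sqrt(len(v)) if len(v) > 1 else 0.0,
            ),
        )
        .reset_index()
    )
    return curves, group
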