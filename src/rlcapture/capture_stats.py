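"""Behavioral statistics linking learning parameters to attentional capture.

Covers the analysis battery run on the capture task: chance-level subject
exclusion, per-condition RT summaries, one-way repeated-measures ANOVA with
a linear trend contrast, Bonferroni-corrected pairwise t-tests, and Spearman
/ partial Spearman correlations between learning rates and distractor
slowing.
"""
from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .task import CAPTURE_CONDITIONS, PAIR_STIMULI

CONDITION_ORDER = ("none", "low", "high")  # increasing distractor value


@dataclass(frozen=True)
class AnovaResult:
    F: float
    df_effect: int
    df_error: int
    p: float
    partial_eta_sq: float


def exclude_chance_performers(
    learning: pd.DataFrame, alpha_level: float = 0.05
) -> tuple[list[str], pd.DataFrame]:
    """Drop subjects whose learning performance is at chance.

    A subject is retained when a one-sided exact binomial test of their
    overall choose-better rate (pooled over pairs; "better" is the stimulus
    with the higher scheduled reward probability) beats 0.5 at `alpha_level`.
    """
    if learning["subject_id"].nunique() < 1:
        raise ValueError("no subjects in learning table")
    better = {pair: stims[0] for pair, stims in PAIR_STIMULI.items()}
    rows = []
    for sid, sub in learning.groupby("subject_id"):
        valid = sub[~sub["omitted"]]
        n = len(valid)
        k = int((valid["chosen"] == valid["pair"].map(better)).sum())
        p = stats.binomtest(k, n, 0.5, alternative="greater").pvalue if n else 1.0
        rows.append(
            {"subject_id": sid, "n_trials": n, "n_better": k,
             "p_value": p, "retained": p < alpha_level}
        )
    report = pd.DataFrame(rows)
    retained = report.loc[report["retained"], "subject_id"].tolist()
    return retained, report


def condition_means(capture: pd.DataFrame) -> pd.DataFrame:
    """Per-subject correct-trial RT means, slowing scores and accuracies.

    slowing_high = mean RT(high) - mean RT(none), likewise for low;
    slowing_diff = mean RT(high) - mean RT(low). RT means use correct trials
    only; accuracy uses all trials.
    """
    rows = []
    for sid, sub in capture.groupby("subject_id"):
        row: dict[str, float | str] = {"subject_id": sid}
        for cond in CAPTURE_CONDITIONS:
            trials = sub[sub["condition"] == cond]
            correct = trials[trials["correct"]]
            if len(correct) == 0:
                raise ValueError(
                    f"subject {sid!r} has no correct {cond!r}-condition trials"
                )
            row[f"mean_rt_{cond}"] = float(correct["rt_ms"].mean())
            row[f"accuracy_{cond}"] = float(trials["correct"].mean())
        row["slowing_high"] = row["mean_rt_high"] - row["mean_rt_none"]
        row["slowing_low"] = row["mean_rt_low"] - row["mean_rt_none"]
        row["slowing_diff"] = row["mean_rt_high"] - row["mean_rt_low"]
        rows.append(row)
    return pd.DataFrame(rows)


def _check_wide(values: pd.DataFrame, min_conditions: int = 2) -> np.ndarray:
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < min_conditions:
        raise ValueError("need a complete subjects x conditions table")
    if np.any(np.isnan(arr)):
        raise ValueError("incomplete table: NaN cells present")
    return arr


def rm_anova_oneway(values: pd.DataFrame) -> AnovaResult:
    """One-way within-subject ANOVA by sums-of-squares partition.

    `values` is wide (rows = subjects, columns = conditions). Partial eta
    squared is SS_condition / (SS_condition + SS_residual). No sphericity
    correction is applied.
    """
    arr = _check_wide(values)
    n, k = arr.shape
    grand = arr.mean()
    ss_cond = n * float(((arr.mean(axis=0) - grand) ** 2).sum())
    ss_subj = k * float(((arr.mean(axis=1) - grand) ** 2).sum())
    ss_total = float(((arr - grand) ** 2).sum())
    ss_resid = ss_total - ss_cond - ss_subj
    df_effect = k - 1
    df_error = (k - 1) * (n - 1)
    ms_cond = ss_cond / df_effect
    ms_resid = ss_resid / df_error
    if ms_resid == 0.0:
        F = float("inf") if ms_cond > 0 else 0.0
        p = 0.0 if ms_cond > 0 else 1.0
    else:
        F = ms_cond / ms_resid
        p = float(stats.f.sf(F, df_effect, df_error))
    eta = ss_cond / (ss_cond + ss_resid) if (ss_cond + ss_resid) > 0 else 0.0
    return AnovaResult(float(F), df_effect, df_error, p, float(eta))


def linear_trend(
    values: pd.DataFrame, order: tuple[str, str, str] = CONDITION_ORDER
) -> AnovaResult:
    """Linear trend over three ordered conditions, weights (-1, 0, +1).

    Each subject's contrast score is tested against 0 with a one-sample F
    (= t^2) on df (1, n_subjects - 1). A zero-variance nonzero contrast is
    the degenerate perfectly-linear case and is reported as F = inf, p = 0.
    """
    if len(order) != 3:
        raise ValueError("linear_trend requires exactly 3 ordered conditions")
    missing = set(order) - set(values.columns)
    if missing:
        raise ValueError(f"missing condition columns {sorted(missing)}")
    arr = _check_wide(values[list(order)], min_conditions=3)
    contrast = arr @ np.array([-1.0, 0.0, 1.0])
    n = len(contrast)
    mean = contrast.mean()
    sd = contrast.std(ddof=1)
    if sd == 0.0:
        if mean == 0.0:
            return AnovaResult(0.0, 1, n - 1, 1.0, 0.0)
        return AnovaResult(float("inf"), 1, n - 1, 0.0, 1.0)
    t = mean / (sd / np.sqrt(n))
    F = t * t
    p = float(stats.f.sf(F, 1, n - 1))
    eta = F / (F + n - 1)
    return AnovaResult(float(F), 1, n - 1, p, float(eta))


def pairwise_bonferroni(values: pd.DataFrame) -> pd.DataFrame:
    """Paired t-tests over all condition pairs, Bonferroni-corrected.

    The family is the set of pairwise comparisons (3 for three conditions);
    corrected p = min(1, raw p * n_pairs).
    """
    arr = _check_wide(values)
    cols = list(values.columns)
    pairs = [(i, j) for i in range(len(cols)) for j in range(i + 1, len(cols))]
    rows = []
    for i, j in pairs:
        res = stats.ttest_rel(arr[:, i], arr[:, j])
        t = float(res.statistic) if np.isfinite(res.statistic) else 0.0
        p_raw = float(res.pvalue) if np.isfinite(res.pvalue) else 1.0
        rows.append(
            {
                "condition_a": cols[i],
                "condition_b": cols[j],
                "t": t,
                "df": arr.shape[0] - 1,
                "p_raw": p_raw,
                "p_bonferroni": min(1.0, p_raw * len(pairs)),
            }
        )
    return pd.DataFrame(rows)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rank correlation (average ranks for ties), two-sided p."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def partial_spearman(x, y, z) -> tuple[float, float]:
    """Partial Spearman correlation of x and y controlling for z.

    All three vectors are rank-transformed (average ranks), then the
    first-order partial Pearson correlation is formed,
    (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2)(1 - r_yz^2)),
    with a two-sided t-approximation p-value on n - 3 df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    if not (x.shape == y.shape == z.shape):
        raise ValueError("x, y and z must have equal length")
    n = x.size
    if n < 6:
        raise ValueError("need at least 6 observations")
    if np.all(z == z[0]):
        raise ValueError("control vector is constant; partial correlation undefined")
    rx, ry, rz = (stats.rankdata(v) for v in (x, y, z))
    r_xy = float(np.corrcoef(rx, ry)[0, 1])
    r_xz = float(np.corrcoef(rx, rz)[0, 1])
    r_yz = float(np.corrcoef(ry, rz)[0, 1])
    denom = np.sqrt((1.0 - r_xz**2) * (1.0 - r_yz**2))
    if denom == 0.0:
        raise ValueError("control vector is collinear with an input")
    rho = (r_xy - r_xz * r_yz) / denom
    rho = float(np.clip(rho, -1.0, 1.0))
    df = n - 3
    if abs(rho) == 1.0:
        return rho, 0.0
    t = rho * np.sqrt(df / (1.0 - rho**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return rho, p


def capture_learning_report(inputs: pd.DataFrame) -> dict:
    """The learning-rate / capture correlation battery.

    `inputs` is one row per subject with columns alpha_high, alpha_low,
    alpha_diff, slowing_high, slowing_low, slowing_diff, and optionally
    ab_accuracy and final_q_a for the control correlations. Returns:

    1. partial Spearman of slowing_high with alpha_high controlling alpha_low;
    2. Spearman of slowing_low with alpha_high;
    3. Spearman of slowing_diff with alpha_diff;
    4. control Spearmans of slowing_high with AB accuracy and final Q(A);
    5. a leave-one-out repeat of (3) dropping the lowest alpha_diff subject.
    """
    required = {"alpha_high", "alpha_low", "alpha_diff",
                "slowing_high", "slowing_low", "slowing_diff"}
    missing = required - set(inputs.columns)
    if missing:
        raise ValueError(f"missing input columns {sorted(missing)}")
    report: dict = {"n_subjects": int(len(inputs))}
    if inputs["slowing_high"].nunique() <= 1:
        report["degenerate"] = "slowing scores are constant"
        return report
    rho, p = partial_spearman(
        inputs["slowing_high"], inputs["alpha_high"], inputs["alpha_low"]
    )
    report["slowing_high_vs_alpha_high_partial"] = {"rho_pcor": rho, "p": p}
    rho, p = spearman(inputs["slowing_low"], inputs["alpha_high"])
    report["slowing_low_vs_alpha_high"] = {"rho": rho, "p": p}
    rho, p = spearman(inputs["slowing_diff"], inputs["alpha_diff"])
    report["slowing_diff_vs_alpha_diff"] = {"rho": rho, "p": p}
    for control in ("ab_accuracy", "final_q_a"):
        if control in inputs.columns:
            rho, p = spearman(inputs["slowing_high"], inputs[control])
            report[f"slowing_high_vs_{control}"] = {"rho": rho, "p": p}
    drop = inputs["alpha_diff"].idxmin()
    loo = inputs.drop(index=drop)
    rho, p = spearman(loo["slowing_diff"], loo["alpha_diff"])
    report["slowing_diff_vs_alpha_diff_loo"] = {"rho": rho, "p": p}
    return report


def write_report_json(report: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(report, indent=1))
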