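"""Stage orchestration: simulate -> fit -> compare -> ppc -> capture.

Each stage reads its upstream artifacts from the output directory and writes
its own; `run_all` chains every stage of the synthetic-study reproduction.
A manifest records the config hash, master seed and artifact list so runs
are auditable and reproducible.
"""
from __future__ import annotations

import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import capture_stats, model_selection, synthetic
from .config import PipelineConfig
from .hierarchical import load_posterior, run_sampler
from .qlearning import ModelSpec, SubjectParams, final_q
from .task import TaskDesign

logger = logging.getLogger(__name__)

STAGES = ("simulate", "fit", "compare", "ppc", "capture", "all")
SCOPES = {"ab": "AB_only", "all": "all_pairs"}


class MissingArtifactError(FileNotFoundError):
    """An upstream artifact is absent; names the stage that produces it."""


def _stage_seed(config: PipelineConfig, label: str) -> int:
    # crc32 keyes the stage label deterministically across processes
    ss = np.random.SeedSequence([config.seed, zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2**31))


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path.name!r}: run the {producer!r} stage first"
        )
    return path


def _update_manifest(outdir: Path, config: PipelineConfig, artifacts: list[str]) -> None:
    mpath = outdir / "manifest.json"
    manifest = json.loads(mpath.read_text()) if mpath.exists() else {}
    manifest["config_hash"] = config.config_hash()
    manifest["seed"] = config.seed
    manifest.setdefault("artifacts", [])
    for a in artifacts:
        if a not in manifest["artifacts"]:
            manifest["artifacts"].append(a)
    mpath.write_text(json.dumps(manifest, indent=1))


def stage_simulate(config: PipelineConfig, outdir: Path) -> list[str]:
    outdir.mkdir(parents=True, exist_ok=True)
    seed = _stage_seed(config, "simulate")
    rng = np.random.default_rng(seed)
    params = synthetic.draw_subject_params(
        config.group_means_probit, config.group_sds_probit, config.n_subjects, rng
    )
    learning = synthetic.simulate_learning_task(params, config.design, rng)
    capture = synthetic.simulate_capture_task(params, config.design, config.coupling, rng)
    synthetic.write_learning_csv(learning, outdir / "learning_trials.csv")
    synthetic.write_capture_csv(capture, outdir / "capture_trials.csv")
    synthetic.write_truth_json(params, outdir / "subject_truth.json")
    config.to_yaml(outdir / "config.yaml")
    logger.info("simulate: seed=%d, %d subjects", seed, config.n_subjects)
    artifacts = ["learning_trials.csv", "capture_trials.csv", "subject_truth.json"]
    _update_manifest(outdir, config, artifacts)
    return artifacts


def _fit_prefix(scope: str, rates: int) -> str:
    return f"fit_{scope}_{rates}a"


def stage_fit(
    config: PipelineConfig, outdir: Path, scope: str = "ab", rates: int = 2
) -> list[str]:
    learning = synthetic.read_learning_csv(
        _require(outdir / "learning_trials.csv", "simulate")
    )
    retained, _ = capture_stats.exclude_chance_performers(learning)
    learning = learning[learning["subject_id"].isin(retained)]
    spec = ModelSpec(n_learning_rates=rates, fit_scope=SCOPES[scope])
    seed = _stage_seed(config, f"fit_{scope}_{rates}")
    post = run_sampler(
        learning,
        config.priors,
        spec,
        n_chains=config.sampler.n_chains,
        n_warmup=config.sampler.n_warmup,
        n_samples=config.sampler.n_samples,
        seed=seed,
        thin=config.sampler.thin,
    )
    prefix = _fit_prefix(scope, rates)
    post.to_csv(outdir / f"{prefix}_samples.csv")
    post.diagnostics_json(outdir / f"{prefix}_diag.json")
    logger.info(
        "fit %s: seed=%d, max Rhat=%.3f, modes=%s",
        prefix, seed, post.max_rhat, post.posterior_modes,
    )
    artifacts = [f"{prefix}_samples.csv", f"{prefix}_diag.json"]
    _update_manifest(outdir, config, artifacts)
    return artifacts


def _load_fit(outdir: Path, scope: str, rates: int):
    prefix = _fit_prefix(scope, rates)
    samples = _require(outdir / f"{prefix}_samples.csv", "fit")
    diag = _require(outdir / f"{prefix}_diag.json", "fit")
    return load_posterior(samples, diag)


def stage_compare(config: PipelineConfig, outdir: Path, scope: str = "ab") -> list[str]:
    learning = synthetic.read_learning_csv(
        _require(outdir / "learning_trials.csv", "simulate")
    )
    fit_2a = _load_fit(outdir, scope, 2)
    fit_1a = _load_fit(outdir, scope, 1)
    learning = learning[learning["subject_id"].isin(fit_2a.subject_ids)]
    comparison = model_selection.compare_models(
        learning, fit_2a, fit_1a, ModelSpec(fit_scope=SCOPES[scope])
    )
    name = f"comparison_{scope}.json"
    comparison.to_json(outdir / name)
    logger.info("compare %s: preferred=%s", scope, comparison.preferred)
    _update_manifest(outdir, config, [name])
    return [name]


def stage_ppc(
    config: PipelineConfig, outdir: Path, scope: str = "ab", n_reps: int = 50
) -> list[str]:
    learning = synthetic.read_learning_csv(
        _require(outdir / "learning_trials.csv", "simulate")
    )
    fit = _load_fit(outdir, scope, 2)
    design = (
        config.design
        if scope == "all"
        else TaskDesign(
            pairs=("AB",),
            high_reward_prob={"AB": config.design.high_reward_prob["AB"]},
            trials_per_pair=config.design.trials_per_pair,
        )
    )
    curves, group = model_selection.posterior_predictive_curves(
        fit,
        design,
        fit.spec,
        n_reps=n_reps,
        seed=_stage_seed(config, f"ppc_{scope}"),
        observed=learning,
    )
    curves.to_csv(outdir / f"curves_{scope}.csv", index=False)
    group.to_csv(outdir / f"curves_{scope}_group.csv", index=False)
    artifacts = [f"curves_{scope}.csv", f"curves_{scope}_group.csv"]
    _update_manifest(outdir, config, artifacts)
    return artifacts


def correlation_inputs(
    learning: pd.DataFrame,
    capture: pd.DataFrame,
    subject_modes: pd.DataFrame,
    spec: ModelSpec,
) -> pd.DataFrame:
    """Per-subject table feeding the correlation battery.

    Combines fitted learning rates, capture slowing scores, AB choose-A
    accuracy and the model's final Q value of stimulus A.
    """
    summary = capture_stats.condition_means(capture).set_index("subject_id")
    rows = []
    for sid, mode_row in subject_modes.iterrows():
        if sid not in summary.index:
            raise ValueError(f"subject {sid!r} missing from capture data")
        sub = learning[learning["subject_id"] == sid].sort_values("trial_index")
        ab = sub[(sub["pair"] == "AB") & (~sub["omitted"])]
        params = SubjectParams(
            alpha_high=float(mode_row["alpha_high"]),
            alpha_low=float(mode_row["alpha_low"]),
            beta=float(mode_row["beta"]),
        )
        rows.append(
            {
                "subject_id": sid,
                "alpha_high": params.alpha_high,
                "alpha_low": params.alpha_low,
                "alpha_diff": params.alpha_high - params.alpha_low,
                "beta": params.beta,
                "slowing_high": summary.loc[sid, "slowing_high"],
                "slowing_low": summary.loc[sid, "slowing_low"],
                "slowing_diff": summary.loc[sid, "slowing_diff"],
                "ab_accuracy": float((ab["chosen"] == "A").mean()),
                "final_q_a": final_q(sub, params, spec)["A"],
            }
        )
    return pd.DataFrame(rows)


def stage_capture(config: PipelineConfig, outdir: Path, scope: str = "ab") -> list[str]:
    learning = synthetic.read_learning_csv(
        _require(outdir / "learning_trials.csv", "simulate")
    )
    capture = synthetic.read_capture_csv(
        _require(outdir / "capture_trials.csv", "simulate")
    )
    fit = _load_fit(outdir, scope, 2)
    retained = fit.subject_ids
    learning = learning[learning["subject_id"].isin(retained)]
    capture = capture[capture["subject_id"].isin(retained)]

    summary = capture_stats.condition_means(capture)
    wide = summary.set_index("subject_id")[
        ["mean_rt_none", "mean_rt_low", "mean_rt_high"]
    ]
    wide.columns = ["none", "low", "high"]
    anova = capture_stats.rm_anova_oneway(wide)
    trend = capture_stats.linear_trend(wide)
    pairwise = capture_stats.pairwise_bonferroni(wide)

    inputs = correlation_inputs(learning, capture, fit.subject_modes, fit.spec)
    battery = capture_stats.capture_learning_report(inputs)

    report = {
        "fit_scope": fit.spec.fit_scope,
        "n_subjects": len(retained),
        "rm_anova": vars(anova),
        "linear_trend": vars(trend),
        "pairwise_bonferroni": pairwise.to_dict(orient="records"),
        "correlations": battery,
        "config_hash": config.config_hash(),
        "seed": config.seed,
    }
    capture_stats.write_report_json(report, outdir / "capture_report.json")
    inputs.to_csv(outdir / "correlation_inputs.csv", index=False)
    artifacts = ["capture_report.json", "correlation_inputs.csv"]
    _update_manifest(outdir, config, artifacts)
    return artifacts


def run_stage(stage: str, config: PipelineConfig, outdir: str | Path, **kwargs) -> list[str]:
    """Run one named stage (or `all`) and return the artifacts it wrote."""
    outdir = Path(outdir)
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; choose from {STAGES}")
    if stage == "simulate":
        return stage_simulate(config, outdir)
    if stage == "fit":
        return stage_fit(config, outdir, **kwargs)
    if stage == "compare":
        return stage_compare(config, outdir, **kwargs)
    if stage == "ppc":
        return stage_ppc(config, outdir, **kwargs)
    if stage == "capture":
        return stage_capture(config, outdir, **kwargs)
    return run_all(config, outdir)


def run_all(config: PipelineConfig, outdir: str | Path) -> list[str]:
    """Full synthetic-study reproduction: both tasks, all four fits,
    model comparison, posterior-predictive curves and the capture report."""
    outdir = Path(outdir)
    artifacts = stage_simulate(config, outdir)
    for scope in ("ab", "all"):
        for rates in (2, 1):
            artifacts += stage_fit(config, outdir, scope=scope, rates=rates)
        artifacts += stage_compare(config, outdir, scope=scope)
    artifacts += stage_ppc(config, outdir, scope="ab")
    artifacts += stage_capture(config, outdir, scope="ab")
    return artifacts
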