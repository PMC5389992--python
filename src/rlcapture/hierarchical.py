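"""Hierarchical Bayesian estimation of the Q-learning model.

Subject-level parameters live on an unbounded probit scale z' and are mapped
to their natural ranges through the probit link: alpha = Phi(z') in (0, 1)
and beta = 100 * Phi(z') in (0, 100). The z' are exchangeable draws from
group-level normals with mean mu_z' and SD delta_z'; the group means carry a
standard-normal prior, mu_z' ~ N(0, 1), and the group SDs a uniform prior,
delta_z' ~ U(1, 1.5).

Posterior sampling uses an adaptive Metropolis-within-Gibbs scheme targeting
`log_posterior` exactly: componentwise random-walk Metropolis on each
subject's z' (proposal scales adapted during warmup only, so the kept draws
leave the posterior invariant), a conjugate Gibbs draw for each group mean,
and an inverse-CDF draw on a fine grid over the uniform support for each
group SD. Convergence is monitored with the split-chain potential scale
reduction factor (Rhat); a fit is flagged converged when max Rhat < 1.05.
Point estimates are posterior modes from a Gaussian kernel density estimate
over the pooled natural-scale draws.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import ndtr
from scipy.stats import gaussian_kde

from . import _kernels
from .qlearning import BETA_SCALE, ModelSpec, _trials_to_arrays

logger = logging.getLogger(__name__)

RHAT_THRESHOLD = 1.05
_LOG_2PI = float(np.log(2.0 * np.pi))


def probit_link(z: float, kind: str) -> float:
    """Map a probit-scale value to the natural scale (alpha or beta)."""
    if kind == "alpha":
        return float(ndtr(z))
    if kind == "beta":
        return float(BETA_SCALE * ndtr(z))
    raise ValueError(f"kind must be 'alpha' or 'beta', got {kind!r}")


@dataclass(frozen=True)
class PriorSpec:
    """Group-level priors: mu_z' ~ N(mean_loc, mean_scale), delta_z' ~ U(lo, hi)."""

    mean_loc: float = 0.0
    mean_scale: float = 1.0
    sd_lower: float = 1.0
    sd_upper: float = 1.5

    def __post_init__(self) -> None:
        if self.mean_scale <= 0:
            raise ValueError("mean_scale must be positive")
        if not 0 < self.sd_lower < self.sd_upper:
            raise ValueError("need 0 < sd_lower < sd_upper")


def _param_dims(spec: ModelSpec) -> tuple[str, ...]:
    if spec.n_learning_rates == 2:
        return ("alpha_high", "alpha_low", "beta")
    return ("alpha", "beta")


def _natural_from_z(z: np.ndarray, spec: ModelSpec) -> tuple[np.ndarray, ...]:
    """Columns of z -> (alpha_high, alpha_low, beta) vectors for the kernel."""
    if spec.n_learning_rates == 2:
        ah = ndtr(z[:, 0])
        al = ndtr(z[:, 1])
        beta = BETA_SCALE * ndtr(z[:, 2])
    else:
        ah = ndtr(z[:, 0])
        al = ah
        beta = BETA_SCALE * ndtr(z[:, 1])
    return np.ascontiguousarray(ah), np.ascontiguousarray(al), np.ascontiguousarray(beta)


class _FitData:
    """Per-subject trial arrays stacked into rectangular kernel inputs."""

    def __init__(self, data: pd.DataFrame, spec: ModelSpec):
        if len(data) == 0:
            raise ValueError("empty learning-trial table")
        self.subject_ids = sorted(data["subject_id"].unique())
        per_subject = []
        for sid in self.subject_ids:
            sub = data[data["subject_id"] == sid].sort_values("trial_index")
            per_subject.append(_trials_to_arrays(sub, spec))
        T = max(arr[0].shape[0] for arr in per_subject)
        n = len(per_subject)
        self.chosen = np.zeros((n, T), dtype=np.int64)
        self.first = np.zeros((n, T), dtype=np.int64)
        self.second = np.ones((n, T), dtype=np.int64)
        self.reward = np.zeros((n, T), dtype=np.int64)
        self.include = np.zeros((n, T), dtype=bool)
        for i, (c, f, s, r, inc) in enumerate(per_subject):
            t = c.shape[0]
            self.chosen[i, :t] = c
            self.first[i, :t] = f
            self.second[i, :t] = s
            self.reward[i, :t] = r
            self.include[i, :t] = inc
        self.n_trials = self.include.sum(axis=1)

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def loglik(self, z: np.ndarray, spec: ModelSpec, q_init: float) -> np.ndarray:
        ah, al, beta = _natural_from_z(z, spec)
        return _kernels.seq_loglik_many(
            self.chosen, self.first, self.second, self.reward, self.include,
            ah, al, beta, q_init,
        )


def _norm_logpdf(x: np.ndarray, loc, scale) -> np.ndarray:
    return -0.5 * (_LOG_2PI + 2.0 * np.log(scale) + ((x - loc) / scale) ** 2)


def log_posterior(
    data: pd.DataFrame,
    state: dict[str, np.ndarray],
    priors: PriorSpec,
    spec: ModelSpec,
) -> float:
    """Unnormalized log posterior density of the hierarchical model.

    ``state`` holds probit-scale values: ``mu`` (P,), ``delta`` (P,) and
    ``z`` (n_subjects, P), with P = n_learning_rates + 1. Returns -inf when
    any group SD falls outside its uniform support.
    """
    fd = _FitData(data, spec)
    P = spec.n_params
    mu = np.asarray(state["mu"], dtype=float)
    delta = np.asarray(state["delta"], dtype=float)
    z = np.asarray(state["z"], dtype=float)
    if mu.shape != (P,) or delta.shape != (P,) or z.shape != (fd.n_subjects, P):
        raise ValueError(
            f"state dimensions do not match {fd.n_subjects} subjects x {P} params"
        )
    if np.any(delta < priors.sd_lower) or np.any(delta > priors.sd_upper):
        return float("-inf")
    ll = float(fd.loglik(z, spec, spec.q_init).sum())
    lp = float(_norm_logpdf(z, mu[None, :], delta[None, :]).sum())
    lp += float(_norm_logpdf(mu, priors.mean_loc, priors.mean_scale).sum())
    lp += -P * float(np.log(priors.sd_upper - priors.sd_lower))
    return ll + lp


@dataclass
class GroupPosterior:
    """MCMC output: per-chain draws, diagnostics, and natural-scale modes."""

    samples: dict[str, np.ndarray]  # name -> (n_chains, n_kept)
    rhat: dict[str, float]
    n_chains: int
    n_warmup: int
    n_kept: int
    subject_ids: list[str]
    spec: ModelSpec
    posterior_modes: dict[str, float] = field(default_factory=dict)
    subject_modes: pd.DataFrame | None = None

    @property
    def max_rhat(self) -> float:
        return max(self.rhat.values())

    @property
    def converged(self) -> bool:
        return self.max_rhat < RHAT_THRESHOLD

    def pooled(self, name: str) -> np.ndarray:
        return self.samples[name].reshape(-1)

    def to_csv(self, path: str | Path) -> None:
        """One row per draw; parameter columns plus chain/draw ids."""
        n = self.n_chains * self.n_kept
        cols = {
            "chain": np.repeat(np.arange(self.n_chains), self.n_kept),
            "draw": np.tile(np.arange(self.n_kept), self.n_chains),
        }
        cols.update({name: self.pooled(name) for name in self.samples})
        pd.DataFrame(cols, index=range(n)).to_csv(path, index=False)

    def diagnostics_json(self, path: str | Path) -> None:
        payload = {
            "n_chains": self.n_chains,
            "n_warmup": self.n_warmup,
            "n_kept": self.n_kept,
            "subject_ids": self.subject_ids,
            "spec": {
                "n_learning_rates": self.spec.n_learning_rates,
                "q_init": self.spec.q_init,
                "fit_scope": self.spec.fit_scope,
            },
            "max_rhat": self.max_rhat,
            "converged": self.converged,
            "rhat": self.rhat,
            "posterior_modes": self.posterior_modes,
            "subject_modes": (
                self.subject_modes.to_dict(orient="index")
                if self.subject_modes is not None
                else None
            ),
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def load_posterior(samples_csv: str | Path, diag_json: str | Path) -> GroupPosterior:
    """Rebuild a GroupPosterior from its persisted samples CSV and diagnostics."""
    diag = json.loads(Path(diag_json).read_text())
    df = pd.read_csv(samples_csv)
    n_chains = int(diag["n_chains"])
    n_kept = int(diag["n_kept"])
    samples = {
        name: df[name].to_numpy().reshape(n_chains, n_kept)
        for name in df.columns
        if name not in ("chain", "draw")
    }
    subject_modes = None
    if diag.get("subject_modes"):
        subject_modes = pd.DataFrame.from_dict(diag["subject_modes"], orient="index")
        subject_modes.index.name = "subject_id"
    return GroupPosterior(
        samples=samples,
        rhat=diag["rhat"],
        n_chains=n_chains,
        n_warmup=int(diag["n_warmup"]),
        n_kept=n_kept,
        subject_ids=list(diag["subject_ids"]),
        spec=ModelSpec(**diag["spec"]),
        posterior_modes=diag.get("posterior_modes", {}),
        subject_modes=subject_modes,
    )


def rhat(chains: np.ndarray) -> float:
    """Split-chain potential scale reduction factor (Gelman-Rubin).

    ``chains`` is (m, n): m >= 2 chains of n >= 4 equal-length draws; a
    single chain is admitted by splitting it in half first. Each chain is
    split in half, between/within variances are pooled over the 2m half
    chains, and sqrt(var_plus / W) is returned.
    """
    chains = np.asarray(chains, dtype=float)
    if chains.ndim != 2:
        raise ValueError("chains must be a 2-D (m, n) array of equal-length chains")
    m, n = chains.shape
    if n < 4:
        raise ValueError("need at least 4 draws per chain")
    half = n // 2
    split = np.concatenate([chains[:, :half], chains[:, n - half :]], axis=0)
    k, n2 = split.shape
    means = split.mean(axis=1)
    W = float(split.var(axis=1, ddof=1).mean())
    B = n2 * float(means.var(ddof=1))
    if W == 0.0:
        return 1.0  # identical constant chains
    var_plus = (n2 - 1) / n2 * W + B / n2
    return float(np.sqrt(var_plus / W))


def posterior_mode(samples: np.ndarray) -> float:
    """KDE posterior mode: Gaussian kernel, normal-reference bandwidth,
    evaluated on a 512-point grid spanning the sample range."""
    samples = np.asarray(samples, dtype=float).ravel()
    if samples.size < 100:
        raise ValueError("posterior_mode requires at least 100 samples")
    lo, hi = float(samples.min()), float(samples.max())
    if lo == hi or np.std(samples) == 0.0:
        return lo
    kde = gaussian_kde(samples, bw_method="silverman")
    grid = np.linspace(lo, hi, 512)
    return float(grid[np.argmax(kde(grid))])


def _run_chain(
    fd: _FitData,
    priors: PriorSpec,
    spec: ModelSpec,
    n_warmup: int,
    n_samples: int,
    rng: np.random.Generator,
    thin: int = 3,
) -> dict[str, np.ndarray]:
    P = spec.n_params
    n = fd.n_subjects
    z = rng.normal(0.0, 0.1, size=(n, P))
    mu = np.zeros(P)
    delta = np.full(P, 0.5 * (priors.sd_lower + priors.sd_upper))
    scale = np.full((n, P), 0.5)
    accepts = np.zeros((n, P))
    adapt_window = 50
    ll = fd.loglik(z, spec, spec.q_init)

    # joint per-subject proposals: covariance learned during warmup to follow
    # the correlated (learning rate, inverse temperature) posterior ridge
    joint_chol = np.tile(np.eye(P) * 0.3, (n, 1, 1))
    joint_logscale = np.zeros(n)
    joint_accepts = np.zeros(n)
    hist_sum = np.zeros((n, P))
    hist_sq = np.zeros((n, P, P))
    hist_n = 0
    cov_start = max(100, n_warmup // 5)

    sd_grid = np.linspace(priors.sd_lower, priors.sd_upper, 513)
    sd_mid = 0.5 * (sd_grid[:-1] + sd_grid[1:])
    sd_cell = sd_grid[1] - sd_grid[0]

    kept_mu = np.empty((n_samples, P))
    kept_delta = np.empty((n_samples, P))
    kept_z = np.empty((n_samples, n, P))

    def z_logprior(zz: np.ndarray) -> np.ndarray:
        return _norm_logpdf(zz, mu[None, :], delta[None, :]).sum(axis=1)

    warmup_sweeps = n_warmup * thin
    for it in range(warmup_sweeps + n_samples * thin):
        for p in range(P):
            z_prop = z.copy()
            z_prop[:, p] = z[:, p] + scale[:, p] * rng.standard_normal(n)
            ll_prop = fd.loglik(z_prop, spec, spec.q_init)
            log_ratio = (
                ll_prop
                - ll
                + _norm_logpdf(z_prop[:, p], mu[p], delta[p])
                - _norm_logpdf(z[:, p], mu[p], delta[p])
            )
            accept = np.log(rng.random(n)) < log_ratio
            z[accept, p] = z_prop[accept, p]
            ll[accept] = ll_prop[accept]
            accepts[:, p] += accept
        # joint move along the adapted covariance
        step = np.einsum(
            "nij,nj->ni", joint_chol, rng.standard_normal((n, P))
        ) * np.exp(joint_logscale)[:, None]
        z_prop = z + step
        ll_prop = fd.loglik(z_prop, spec, spec.q_init)
        log_ratio = ll_prop - ll + z_logprior(z_prop) - z_logprior(z)
        accept = np.log(rng.random(n)) < log_ratio
        z[accept] = z_prop[accept]
        ll[accept] = ll_prop[accept]
        joint_accepts += accept
        # independence proposal from the group prior: lets a subject jump
        # between distant regions of a flat likelihood ridge
        z_prop = rng.normal(mu[None, :], delta[None, :], size=(n, P))
        ll_prop = fd.loglik(z_prop, spec, spec.q_init)
        accept = np.log(rng.random(n)) < ll_prop - ll
        z[accept] = z_prop[accept]
        ll[accept] = ll_prop[accept]
        if it < warmup_sweeps:
            hist_sum += z
            hist_sq += z[:, :, None] * z[:, None, :]
            hist_n += 1
            if (it + 1) % adapt_window == 0:
                rate = accepts / adapt_window
                scale *= np.exp(0.9 * (rate - 0.35))
                np.clip(scale, 1e-3, 5.0, out=scale)
                accepts[:] = 0.0
                jrate = joint_accepts / adapt_window
                joint_logscale += 0.9 * (jrate - 0.3)
                np.clip(joint_logscale, -4.0, 2.0, out=joint_logscale)
                joint_accepts[:] = 0.0
                if hist_n >= cov_start:
                    mean = hist_sum / hist_n
                    cov = hist_sq / hist_n - mean[:, :, None] * mean[:, None, :]
                    cov += 1e-6 * np.eye(P)[None, :, :]
                    # 2.38^2/P is the classic adaptive-Metropolis scaling
                    joint_chol = np.linalg.cholesky(2.38**2 / P * cov)
        # group means: conjugate normal-normal Gibbs draw
        prec = n / delta**2 + 1.0 / priors.mean_scale**2
        mean = (z.sum(axis=0) / delta**2 + priors.mean_loc / priors.mean_scale**2) / prec
        mu = rng.normal(mean, np.sqrt(1.0 / prec))
        # group SDs: inverse-CDF draw on a fine grid over the uniform support
        S = ((z - mu[None, :]) ** 2).sum(axis=0)
        for p in range(P):
            logw = -n * np.log(sd_mid) - S[p] / (2.0 * sd_mid**2)
            w = np.exp(logw - logw.max())
            cdf = np.cumsum(w)
            u = rng.random() * cdf[-1]
            idx = int(np.searchsorted(cdf, u))
            delta[p] = sd_mid[idx] + (rng.random() - 0.5) * sd_cell
        if it >= warmup_sweeps and (it - warmup_sweeps) % thin == thin - 1:
            j = (it - warmup_sweeps) // thin
            kept_mu[j] = mu
            kept_delta[j] = delta
            kept_z[j] = z
    return {"mu": kept_mu, "delta": kept_delta, "z": kept_z}


def run_sampler(
    data: pd.DataFrame,
    priors: PriorSpec,
    spec: ModelSpec,
    n_chains: int = 4,
    n_warmup: int = 1000,
    n_samples: int = 1000,
    seed: int = 0,
    thin: int = 5,
) -> GroupPosterior:
    """Sample the hierarchical posterior and summarize it.

    Runs ``n_chains`` independent chains (>= 2, required for Rhat), computes
    split-Rhat for every sampled parameter, and reports natural-scale KDE
    posterior modes for the group means and every subject's parameters.
    """
    if n_chains < 2:
        raise ValueError("n_chains must be at least 2")
    if n_warmup < 1 or n_samples < 1:
        raise ValueError("n_warmup and n_samples must be positive")
    fd = _FitData(data, spec)
    dims = _param_dims(spec)
    child_seeds = np.random.SeedSequence(seed).spawn(n_chains)
    chains = [
        _run_chain(fd, priors, spec, n_warmup, n_samples, np.random.default_rng(s), thin)
        for s in child_seeds
    ]

    samples: dict[str, np.ndarray] = {}
    for p, dim in enumerate(dims):
        samples[f"mu_{dim}"] = np.stack([c["mu"][:, p] for c in chains])
        samples[f"delta_{dim}"] = np.stack([c["delta"][:, p] for c in chains])
        for i, sid in enumerate(fd.subject_ids):
            samples[f"z_{dim}[{sid}]"] = np.stack([c["z"][:, i, p] for c in chains])

    rhats = {name: rhat(draws) for name, draws in samples.items()}

    # Group-level natural-scale estimate: the posterior of the subject
    # average, mean_i of Phi(z'_i). With a nonlinear link, Phi(mu) is the
    # median subject's parameter rather than the group mean of parameters,
    # so the subject average is the quantity summarized as "the group
    # learning rate"; Phi(mu) is kept alongside as the location summary.
    modes: dict[str, float] = {}
    for p, dim in enumerate(dims):
        scale_f = BETA_SCALE if dim == "beta" else 1.0
        subj = np.stack(
            [samples[f"z_{dim}[{sid}]"] for sid in fd.subject_ids]
        )  # (n_subjects, n_chains, n_kept)
        group_avg = (ndtr(subj) * scale_f).mean(axis=0).ravel()
        modes[dim] = posterior_mode(group_avg)
        modes[f"{dim}_location"] = posterior_mode(ndtr(samples[f"mu_{dim}"].ravel()) * scale_f)
    subject_rows = {}
    for i, sid in enumerate(fd.subject_ids):
        row = {}
        for dim in dims:
            kind = "beta" if dim == "beta" else "alpha"
            z_draws = samples[f"z_{dim}[{sid}]"].ravel()
            natural = ndtr(z_draws) * (BETA_SCALE if kind == "beta" else 1.0)
            row[dim] = posterior_mode(natural)
        subject_rows[sid] = row
    subject_modes = pd.DataFrame.from_dict(subject_rows, orient="index")
    subject_modes.index.name = "subject_id"

    post = GroupPosterior(
        samples=samples,
        rhat=rhats,
        n_chains=n_chains,
        n_warmup=n_warmup,
        n_kept=n_samples,
        subject_ids=fd.subject_ids,
        spec=spec,
        posterior_modes=modes,
        subject_modes=subject_modes,
    )
    if not post.converged:
        logger.warning(
            "max Rhat %.3f >= %.2f: chains may not have converged",
            post.max_rhat,
            RHAT_THRESHOLD,
        )
    return post
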