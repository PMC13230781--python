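"""Hierarchical Bayesian estimation of bank models on a cohort.

Each free parameter ``phi`` of a model is given a group-level normal
population, ``phi_i ~ N(mu_phi, sigma_phi)`` on an unbounded scale, with
weakly informative hyperpriors ``mu_phi ~ N(0, 1)`` and
``sigma_phi ~ half-Cauchy(0, 3)``.  Subject-level values are parameterised
non-centrally (``phi_i = mu + sigma * z_i``, ``z_i ~ N(0, 1)``) and mapped
into their declared bounds through the standard-normal CDF; the unbounded
preference parameter passes through unchanged.

Posteriors are approximated by MCMC: coordinate-wise slice sampling within
Gibbs sweeps over the hyperparameters and latent offsets, run as several
independent chains.  Slice sampling needs no step-size tuning and its
per-coordinate moves are compiled, so the default configuration matching
the study (4 chains x 3000 warmup x 1000 retained = 4000 draws) runs at
desk scale.  Convergence is judged by the split-R-hat statistic with the
conventional 1.1 threshold.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.special import ndtr

from . import _kernels
from .models import MODEL_BANK, PARAM_BOUNDS, ModelSpec, get_model
from .task import DesignSpec, Session

logger = logging.getLogger(__name__)

__all__ = [
    "SamplerConfig",
    "PRESETS",
    "HierPrior",
    "FitResult",
    "transform_to_bounds",
    "fit_hierarchical",
    "split_rhat",
    "check_convergence",
    "extract_pointwise_ll",
]

#: params5 slot of each named parameter in the compiled kernels.
_SLOT = {"alpha": 0, "alpha_h": 0, "alpha_l": 1, "beta": 2, "kappa": 3, "theta": 4}


@dataclass(frozen=True)
class SamplerConfig:
    chains: int = 4
    warmup: int = 3000
    draws: int = 1000

    def __post_init__(self):
        if self.chains < 1 or self.warmup < 0 or self.draws < 1:
            raise ValueError(f"invalid sampler configuration {self}")

    @property
    def total_draws(self) -> int:
        return self.chains * self.draws


#: ``"paper"`` matches the study's sampler settings; ``"ci"`` and
#: ``"recovery"`` are reduced presets for desk-scale runs.
PRESETS: dict[str, SamplerConfig] = {
    "paper": SamplerConfig(chains=4, warmup=3000, draws=1000),
    "ci": SamplerConfig(chains=2, warmup=500, draws=500),
    "recovery": SamplerConfig(chains=2, warmup=300, draws=300),
}


@dataclass(frozen=True)
class HierPrior:
    """Scales of the group-level hyperpriors (same for every parameter by
    default; override per parameter via the dicts)."""

    mu_scale: float = 1.0
    sigma_scale: float = 3.0
    mu_scales: dict = field(default_factory=dict)
    sigma_scales: dict = field(default_factory=dict)

    def scales_for(self, param: str) -> tuple[float, float]:
        return (
            float(self.mu_scales.get(param, self.mu_scale)),
            float(self.sigma_scales.get(param, self.sigma_scale)),
        )


def transform_to_bounds(raw, lower: Optional[float], upper: Optional[float]):
    """Map unbounded values into ``[lower, upper]`` via the probit CDF.

    ``lower``/``upper`` of ``None`` denote an unbounded parameter, which
    passes through unchanged.
    """
    raw = np.asarray(raw, dtype=float)
    if lower is None or upper is None:
        out = raw
    else:
        if not lower < upper:
            raise ValueError("lower must be < upper")
        out = lower + (upper - lower) * ndtr(raw)
    return out.item() if out.ndim == 0 else out


def _pack_sessions(sessions: Sequence[Session]):
    N = len(sessions)
    tlen = np.array([len(s) for s in sessions], dtype=np.int64)
    Tmax = int(tlen.max())
    choices = np.zeros((N, Tmax), dtype=np.int64)
    oppc = np.zeros((N, Tmax), dtype=np.int64)
    oppi = np.zeros((N, Tmax), dtype=np.int64)
    rew = np.zeros((N, Tmax), dtype=np.float64)
    for i, s in enumerate(sessions):
        arrs = s.arrays()
        choices[i, : tlen[i]] = arrs["choice"]
        oppc[i, : tlen[i]] = arrs["opponent_choice"]
        oppi[i, : tlen[i]] = arrs["opponent_index"]
        rew[i, : tlen[i]] = arrs["reward"]
    return choices, oppc, oppi, rew, tlen


def _model_codes(model: ModelSpec):
    names = model.free_params
    K = len(names)
    slots = np.array([_SLOT[n] for n in names], dtype=np.int64)
    lo = np.zeros(K)
    hi = np.zeros(K)
    ident = np.zeros(K, dtype=np.int64)
    for k, n in enumerate(names):
        bounds = PARAM_BOUNDS[n]
        if bounds is None:
            ident[k] = 1
        else:
            lo[k], hi[k] = bounds
    fam = 0 if model.update_family == "reward" else 1
    tie = 1 if model.n_alphas == 1 else 0
    return names, slots, lo, hi, ident, tie, fam, int(model.frozen), int(model.has_kappa)


@dataclass
class FitResult:
    """Posterior draws, pointwise log-likelihoods and diagnostics of one fit.

    Draw arrays are indexed ``(chain, draw, ...)``; ``subject_params`` holds
    natural-scale subject-level values, ``group_mu_raw``/``group_log_sigma``
    the sampled hyper coordinates on the unbounded scale.
    """

    model: ModelSpec
    param_names: tuple[str, ...]
    subject_ids: list[str]
    group_mu_raw: np.ndarray  # (chains, draws, K)
    group_log_sigma: np.ndarray  # (chains, draws, K)
    z: np.ndarray  # (chains, draws, N, K)
    subject_params: np.ndarray  # (chains, draws, N, K), natural scale
    pointwise_ll: np.ndarray  # (chains, draws, N, T)
    tlen: np.ndarray
    config: SamplerConfig
    seed: int
    prior: HierPrior
    rhat: Optional[pd.DataFrame] = None

    @property
    def n_draws_total(self) -> int:
        return self.group_mu_raw.shape[0] * self.group_mu_raw.shape[1]

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    def group_mean_natural(self) -> dict[str, float]:
        """Posterior mean of the bound-transformed group-level location."""
        out = {}
        for k, name in enumerate(self.param_names):
            bounds = PARAM_BOUNDS[name]
            draws = self.group_mu_raw[..., k]
            if bounds is not None:
                draws = transform_to_bounds(draws, *bounds)
            out[name] = float(np.mean(draws))
        return out

    def subject_posterior_means(self) -> pd.DataFrame:
        means = self.subject_params.mean(axis=(0, 1))  # (N, K)
        return pd.DataFrame(means, index=self.subject_ids, columns=list(self.param_names))

    def ll_matrix(self) -> np.ndarray:
        """Pointwise log-likelihood as ``(chains, draws, n_obs)`` over valid
        trials (observation = one trial, subjects concatenated)."""
        if not np.all(self.tlen == self.tlen[0]):
            raise ValueError("sessions have unequal trial counts")
        c, d, N, T = self.pointwise_ll.shape
        return self.pointwise_ll.reshape(c, d, N * T)

    def max_rhat(self) -> float:
        if self.rhat is None:
            raise ValueError("diagnostics not computed")
        return float(self.rhat["rhat"].max())

    def save(self, path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        np.savez_compressed(
            path / "draws.npz",
            group_mu_raw=self.group_mu_raw,
            group_log_sigma=self.group_log_sigma,
            z=self.z,
            subject_params=self.subject_params,
            pointwise_ll=self.pointwise_ll,
            tlen=self.tlen,
        )
        meta = {
            "model": self.model.name,
            "param_names": list(self.param_names),
            "subject_ids": list(self.subject_ids),
            "config": {"chains": self.config.chains, "warmup": self.config.warmup,
                       "draws": self.config.draws},
            "seed": int(self.seed),
            "prior": {"mu_scale": self.prior.mu_scale, "sigma_scale": self.prior.sigma_scale},
            "max_rhat": None if self.rhat is None else self.max_rhat(),
        }
        (path / "meta.json").write_text(json.dumps(meta, indent=2))
        if self.rhat is not None:
            self.rhat.to_csv(path / "rhat.csv", index=False)

    @classmethod
    def load(cls, path) -> "FitResult":
        path = Path(path)
        meta = json.loads((path / "meta.json").read_text())
        arrs = np.load(path / "draws.npz")
        fit = cls(
            model=get_model(meta["model"]),
            param_names=tuple(meta["param_names"]),
            subject_ids=list(meta["subject_ids"]),
            group_mu_raw=arrs["group_mu_raw"],
            group_log_sigma=arrs["group_log_sigma"],
            z=arrs["z"],
            subject_params=arrs["subject_params"],
            pointwise_ll=arrs["pointwise_ll"],
            tlen=arrs["tlen"],
            config=SamplerConfig(**meta["config"]),
            seed=meta["seed"],
            prior=HierPrior(
                mu_scale=meta["prior"]["mu_scale"], sigma_scale=meta["prior"]["sigma_scale"]
            ),
        )
        rhat_path = path / "rhat.csv"
        if rhat_path.exists():
            fit.rhat = pd.read_csv(rhat_path)
        return fit


def fit_hierarchical(
    model: Union[ModelSpec, str],
    sessions: Sequence[Session],
    config: Union[SamplerConfig, str] = "paper",
    seed: int = 0,
    prior: Optional[HierPrior] = None,
    design: Optional[DesignSpec] = None,
) -> FitResult:
    """Fit one bank model to a cohort of sessions.

    All sessions must share a design (payoff matrix and reward scale).  The
    returned :class:`FitResult` carries posterior draws of group- and
    subject-level parameters, the per-draw pointwise log-likelihood of every
    trial (for PSIS-LOO), and a split-R-hat table; non-convergence
    (max R-hat >= 1.1) is flagged in the log, not fatal.
    """
    if isinstance(model, str):
        model = get_model(model)
    if isinstance(config, str):
        config = PRESETS[config]
    if not sessions:
        raise ValueError("need at least one session")
    prior = prior or HierPrior()
    if design is None:
        design = sessions[0].design
        if design is None:
            raise ValueError("sessions carry no design; pass design= explicitly")

    choices, oppc, oppi, rew, tlen = _pack_sessions(sessions)
    names, slots, lo, hi, ident, tie, fam, frozen, has_kappa = _model_codes(model)
    A = design.payoff.sg - design.payoff.gg
    B = (design.payoff.ss - design.payoff.sg) - (design.payoff.gs - design.payoff.gg)
    rscale = float(design.reward_scale)
    mu_scale = np.array([prior.scales_for(n)[0] for n in names])
    sigma_scale = np.array([prior.scales_for(n)[1] for n in names])

    chain_seeds = np.random.SeedSequence(seed).generate_state(config.chains).astype(np.int64)
    mu_chains, ls_chains, z_chains = [], [], []
    for c in range(config.chains):
        mu_d, ls_d, z_d = _kernels.run_chain(
            int(chain_seeds[c]) % (2**31), config.warmup, config.draws,
            slots, lo, hi, ident, tie, fam, frozen, has_kappa,
            choices, oppc, oppi, rew, tlen, A, B, rscale, mu_scale, sigma_scale,
        )
        mu_chains.append(mu_d)
        ls_chains.append(ls_d)
        z_chains.append(z_d)
    group_mu = np.stack(mu_chains)  # (chains, draws, K)
    group_ls = np.stack(ls_chains)
    zarr = np.stack(z_chains)  # (chains, draws, N, K)

    raw = group_mu[:, :, None, :] + np.exp(group_ls)[:, :, None, :] * zarr
    natural = raw.copy()
    for k in range(len(names)):
        if not ident[k]:
            natural[..., k] = lo[k] + (hi[k] - lo[k]) * ndtr(raw[..., k])

    pw_chains = [
        _kernels.pointwise_all(
            mu_chains[c], ls_chains[c], z_chains[c], slots, lo, hi, ident, tie,
            fam, frozen, has_kappa, choices, oppc, oppi, rew, tlen, A, B, rscale,
        )
        for c in range(config.chains)
    ]
    pointwise = np.stack(pw_chains)

    fit = FitResult(
        model=model,
        param_names=tuple(names),
        subject_ids=[s.subject_id for s in sessions],
        group_mu_raw=group_mu,
        group_log_sigma=group_ls,
        z=zarr,
        subject_params=natural,
        pointwise_ll=pointwise,
        tlen=tlen,
        config=config,
        seed=seed,
        prior=prior,
    )
    if config.chains >= 2:
        ok, table = check_convergence(fit)
        fit.rhat = table
        if not ok:
            logger.warning(
                "%s fit did not converge: max split-R-hat = %.3f",
                model.name, table["rhat"].max(),
            )
    return fit


def split_rhat(draws: np.ndarray) -> float:
    """Split-R-hat of one scalar parameter from ``(chains, draws)`` samples.

    Each chain is split in half and the classic potential-scale-reduction
    statistic computed over the resulting half-chains.
    """
    x = np.asarray(draws, dtype=float)
    if x.ndim != 2:
        raise ValueError("expected (chains, draws)")
    c, n = x.shape
    if c < 2:
        raise ValueError("split-R-hat needs at least 2 chains")
    half = n // 2
    if half < 2:
        raise ValueError("chains too short to split")
    halves = np.concatenate([x[:, :half], x[:, half : 2 * half]], axis=0)
    W = halves.var(axis=1, ddof=1).mean()
    B = half * halves.mean(axis=1).var(ddof=1)
    if W == 0.0:
        return 1.0 if B == 0.0 else np.inf
    var_plus = (half - 1) / half * W + B / half
    return float(np.sqrt(var_plus / W))


def check_convergence(fit: FitResult, threshold: float = 1.1) -> tuple[bool, pd.DataFrame]:
    """Split-R-hat for every group- and subject-level parameter.

    Passes iff the maximum R-hat is below ``threshold`` (1.1 by
    convention).  Raises for single-chain fits, where R-hat is undefined.
    """
    if fit.group_mu_raw.shape[0] < 2:
        raise ValueError("convergence check requires at least 2 chains")
    rows = []
    for k, name in enumerate(fit.param_names):
        rows.append({"param": f"mu_{name}", "rhat": split_rhat(fit.group_mu_raw[:, :, k])})
        rows.append(
            {"param": f"log_sigma_{name}", "rhat": split_rhat(fit.group_log_sigma[:, :, k])}
        )
        for i, sid in enumerate(fit.subject_ids):
            rows.append(
                {
                    "param": f"{name}[{sid}]",
                    "rhat": split_rhat(fit.subject_params[:, :, i, k]),
                }
            )
    table = pd.DataFrame(rows)
    return bool(table["rhat"].max() < threshold), table


def extract_pointwise_ll(fit: FitResult) -> np.ndarray:
    """Pointwise log-likelihood flattened to ``(draws, subjects, trials)``."""
    c, d, N, T = fit.pointwise_ll.shape
    return fit.pointwise_ll.reshape(c * d, N, T)
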