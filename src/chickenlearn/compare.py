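"""PSIS-LOO model comparison, stacking weights, and family-level selection.

Models are scored by the leave-one-out information criterion
``LOOIC = -2 * elpd_loo`` computed by Pareto-smoothed importance sampling
(one observation = one trial).  Within each learning family (reward M1,
belief M2, second-order belief M3) the sub-models are combined by stacking
— simplex weights maximising the pooled leave-one-out log predictive
density — and families are compared by the predictive score of their
stacked mixtures.  The best family's lowest-LOOIC member is the selected
model; the non-learning (M0) and preference-only (M4) baselines are
reported alongside, since a credible learning model must beat both.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence, Union

import arviz as az
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp, softmax

from .hier import FitResult

logger = logging.getLogger(__name__)

__all__ = [
    "LooSummary",
    "ComparisonTable",
    "psis_loo",
    "stacking_weights",
    "family_comparison",
    "family_of",
    "PARETO_K_THRESHOLD",
]

PARETO_K_THRESHOLD = 0.7

#: Families used for model selection; M0 and M4 act as baselines.
_FAMILIES = {"M0": "none", "M1": "reward", "M2": "belief", "M3": "belief2", "M4": "pref_only"}
_LEARNING_FAMILIES = ("reward", "belief", "belief2")


def family_of(name: str) -> str:
    prefix = name.split("-")[0]
    try:
        return _FAMILIES[prefix]
    except KeyError:
        raise ValueError(f"cannot infer family of model {name!r}") from None


@dataclass
class LooSummary:
    """PSIS-LOO summary of one model on one dataset."""

    name: str
    elpd: float
    se: float
    pointwise: np.ndarray  # per-observation elpd_loo
    pareto_k: np.ndarray
    n_bad_k: int

    @property
    def looic(self) -> float:
        return -2.0 * self.elpd


def _as_ll_matrix(fit: Union[FitResult, np.ndarray]) -> np.ndarray:
    """Coerce input to a (chains, draws, n_obs) log-likelihood array."""
    if isinstance(fit, FitResult):
        return fit.ll_matrix()
    arr = np.asarray(fit, dtype=float)
    if arr.ndim == 2:  # (draws, n_obs): treat as one chain
        arr = arr[None, ...]
    if arr.ndim != 3:
        raise ValueError("expected (chains, draws, n_obs) pointwise log-likelihood")
    return arr


def psis_loo(fit: Union[FitResult, np.ndarray], name: str = "") -> LooSummary:
    """Pareto-smoothed importance-sampling LOO of one model.

    Accepts a :class:`FitResult` or a raw pointwise log-likelihood array
    with draws over trials.  Observations with Pareto shape k above 0.7 are
    counted in ``n_bad_k``.
    """
    ll = _as_ll_matrix(fit)
    if not np.all(np.isfinite(ll)):
        raise ValueError("non-finite pointwise log-likelihood")
    if isinstance(fit, FitResult) and not name:
        name = fit.model.name

    c, d, n_obs = ll.shape
    S = c * d
    flat = ll.reshape(S, n_obs)
    if isinstance(fit, FitResult) and c >= 2:
        # relative MCMC efficiency of the sampler from the hyper draws
        ess = [
            float(az.ess(fit.group_mu_raw[..., k]))
            for k in range(fit.group_mu_raw.shape[-1])
        ]
        reff = float(np.clip(np.mean(ess) / S, 1e-3, 1.0))
    else:
        reff = 1.0
    with np.errstate(invalid="ignore", divide="ignore"):
        lw, k = az.psislw(-flat.T, reff)  # (n_obs, S)
    lw = np.asarray(lw, dtype=float)
    k = np.asarray(k, dtype=float)
    # Observations whose likelihood is (near-)constant across draws carry
    # constant importance ratios: no smoothing needed, shape k undefined.
    span = flat.max(axis=0) - flat.min(axis=0)
    degenerate = span < 1e-8
    lw[degenerate] = -np.log(S)
    k[degenerate] = -np.inf
    # Residual Pareto-fit failures: fall back to unsmoothed uniform weights
    # and flag the observation as unreliable.
    broken = ~np.all(np.isfinite(lw), axis=1)
    if broken.any():
        lw[broken] = -np.log(S)
        k[broken] = np.inf
    pointwise = logsumexp(flat.T + lw, axis=1)
    elpd = float(pointwise.sum())
    se = float(np.sqrt(n_obs * pointwise.var(ddof=1))) if n_obs > 1 else 0.0
    n_bad = int(np.sum(k > PARETO_K_THRESHOLD))
    if n_bad:
        logger.info("%s: %d observations with Pareto k > %.1f", name, n_bad, PARETO_K_THRESHOLD)
    return LooSummary(
        name=name,
        elpd=elpd,
        se=se,
        pointwise=np.asarray(pointwise, dtype=float),
        pareto_k=k,
        n_bad_k=n_bad,
    )


def stacking_weights(pointwise: Sequence[np.ndarray]) -> np.ndarray:
    """Stacking weights over models from per-observation elpd_loo vectors.

    Maximises ``sum_n log sum_k w_k exp(elpd[n, k])`` over the simplex via a
    softmax parameterisation.  Identical models receive equal weight (the
    optimiser is initialised uniformly and the objective is then flat).
    """
    mats = [np.asarray(p, dtype=float).ravel() for p in pointwise]
    if len(mats) < 2:
        raise ValueError("stacking needs at least 2 models")
    n_obs = {m.size for m in mats}
    if len(n_obs) != 1:
        raise ValueError("models were scored on different observation sets")
    E = np.column_stack(mats)  # (n_obs, K)
    K = E.shape[1]
    # subtract per-observation max for numerical stability
    shift = E.max(axis=1, keepdims=True)
    D = np.exp(E - shift)

    def neg_obj(a):
        w = softmax(np.concatenate([a, [0.0]]))
        dens = D @ w
        return -np.sum(np.log(dens))

    def grad(a):
        w = softmax(np.concatenate([a, [0.0]]))
        dens = D @ w
        gw = -(D / dens[:, None]).sum(axis=0)  # d(-obj)/dw
        jac = np.diag(w) - np.outer(w, w)  # dw/da (full K)
        return (jac @ gw)[:-1]

    res = minimize(neg_obj, np.zeros(K - 1), jac=grad, method="BFGS")
    w = softmax(np.concatenate([res.x, [0.0]]))
    return w


def _stacked_lpd(pointwise: Sequence[np.ndarray], weights: np.ndarray) -> float:
    """Pooled log predictive density of the stacked mixture."""
    E = np.column_stack([np.asarray(p, dtype=float).ravel() for p in pointwise])
    logw = np.log(np.maximum(weights, 1e-300))
    return float(np.sum(logsumexp(E + logw[None, :], axis=1)))


@dataclass
class ComparisonTable:
    """Ranked comparison across the fitted bank."""

    table: pd.DataFrame  # model, family, elpd, se, looic, weight columns
    pairwise: pd.DataFrame  # elpd differences with SEs and decisiveness
    family_scores: dict[str, float]
    family_weights: dict[str, dict[str, float]]
    selected_family: Optional[str]
    selected_model: Optional[str]
    tie: bool = False


def _pairwise(loos: list[LooSummary]) -> pd.DataFrame:
    rows = []
    for i, a in enumerate(loos):
        for b in loos[i + 1 :]:
            diff = a.pointwise - b.pointwise
            d_elpd = float(diff.sum())
            se = float(np.sqrt(diff.size * diff.var(ddof=1))) if diff.size > 1 else 0.0
            rows.append(
                {
                    "model_a": a.name,
                    "model_b": b.name,
                    "d_elpd": d_elpd,
                    "se": se,
                    "decisive": bool(abs(d_elpd) > 2 * se),
                }
            )
    return pd.DataFrame(rows)


def family_comparison(
    fits: dict[str, Union[FitResult, np.ndarray]]
) -> ComparisonTable:
    """Reproduce the selection logic over a fitted (sub)bank.

    Steps: PSIS-LOO per model; stacking weights within each learning family
    present; family-level predictive score = pooled log density of the
    family's stacked mixture; winning family = highest score; selected model
    = lowest LOOIC within the winning family.  Baselines (M0, M4) appear in
    the table but do not compete at the family level.  An exact tie between
    top family scores is reported, not silently broken.
    """
    if not fits:
        raise ValueError("no fits given")
    loos = {name: psis_loo(fit, name=name) for name, fit in fits.items()}

    rows = []
    for name, loo in loos.items():
        rows.append(
            {
                "model": name,
                "family": family_of(name),
                "elpd_loo": loo.elpd,
                "se": loo.se,
                "looic": loo.looic,
                "n_bad_k": loo.n_bad_k,
            }
        )
    table = pd.DataFrame(rows).sort_values("looic").reset_index(drop=True)

    family_weights: dict[str, dict[str, float]] = {}
    family_scores: dict[str, float] = {}
    for fam in _LEARNING_FAMILIES:
        members = [n for n in loos if family_of(n) == fam]
        if not members:
            continue
        if len(members) == 1:
            weights = np.array([1.0])
        else:
            weights = stacking_weights([loos[n].pointwise for n in members])
        family_weights[fam] = dict(zip(members, weights.tolist()))
        family_scores[fam] = _stacked_lpd([loos[n].pointwise for n in members], weights)

    # pooled stacking weights across every fitted model, for transparency
    if len(loos) >= 2:
        all_names = list(loos)
        all_w = stacking_weights([loos[n].pointwise for n in all_names])
        table = table.merge(
            pd.DataFrame({"model": all_names, "stacking_weight_all": all_w}), on="model"
        )

    selected_family = selected_model = None
    tie = False
    if family_scores:
        ranked = sorted(family_scores.items(), key=lambda kv: kv[1], reverse=True)
        if len(ranked) > 1 and abs(ranked[0][1] - ranked[1][1]) < 1e-9:
            tie = True
            logger.warning("family scores tied: %s", ranked[:2])
        selected_family = ranked[0][0]
        members = table[table["family"] == selected_family]
        selected_model = members.sort_values("looic").iloc[0]["model"]

    return ComparisonTable(
        table=table,
        pairwise=_pairwise(list(loos.values())),
        family_scores=family_scores,
        family_weights=family_weights,
        selected_family=selected_family,
        selected_model=selected_model,
        tie=tie,
    )
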