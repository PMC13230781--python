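"""Model bank for trial-by-trial learning in the repeated Chicken game.

The bank contains twelve models organised in five families:

* ``M0`` — non-learning baseline: a delta-rule learner with its learning
  rate fixed to zero, leaving the inverse temperature ``beta`` as the only
  parameter.  With zero-initialised action values this is a coin-flip model.
* ``M1-1/2/3`` — reward-based (Rescorla–Wagner) learners that update the
  value of the *chosen* action from the received payoff,
  ``V[t+1] = V[t] + alpha * (R[t] - V[t])``.
* ``M2-1/2/3`` — belief-based (fictitious-play) learners that track the
  opponent's probability ``p`` of swerving,
  ``p[t+1] = p[t] + alpha * (O[t] - p[t])``, and derive action values from
  the payoff matrix.
* ``M3-1/2/3`` — second-order-belief learners that additionally correct
  ``p`` by the discrepancy between the participant's own action and the
  opponent's inferred estimate ``q`` of that action (influence weight
  ``kappa``).
* ``M4-1/2`` — preference-only ablations: no trial-by-trial updating, a
  constant choice probability ``sigmoid(beta * EV0 + theta)`` with ``EV0``
  frozen at the initial state of the reward (M4-1) or belief (M4-2) family.

Within each learning family the three sub-models are: one learning rate
(``-1``), separate learning rates per opponent (``-2``), and separate rates
plus a swerve-preference bias ``theta`` inside the logistic choice rule
(``-3``).

Choice coding is ``1 = Swerve`` (cooperate) and ``0 = Go straight``
everywhere; opponent and participant state is tracked separately per
opponent, so trials against one opponent never touch the other's state.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional

import numpy as np

__all__ = [
    "SWERVE",
    "GO_STRAIGHT",
    "OPPONENTS",
    "ModelSpec",
    "ParamSet",
    "LearnerState",
    "MODEL_BANK",
    "PARAM_BOUNDS",
    "BELIEF_EPS",
    "get_model",
    "belief_ev_coeffs",
    "init_state",
    "reward_update",
    "belief_update",
    "second_order_q",
    "belief2_update",
    "expected_value",
    "choice_prob",
    "session_loglik",
]

SWERVE: int = 1
GO_STRAIGHT: int = 0

#: Opponent labels in canonical index order (0 = HCO, 1 = LCO).
OPPONENTS: tuple[str, str] = ("HCO", "LCO")

#: Clipping bound keeping beliefs strictly inside (0, 1) so the logit in the
#: second-order inference stays finite.
BELIEF_EPS: float = 1e-6

#: Declared support of each free parameter; ``None`` means unbounded
#: (identity transform in the hierarchical model).
PARAM_BOUNDS: dict[str, Optional[tuple[float, float]]] = {
    "alpha": (0.0, 1.0),
    "alpha_h": (0.0, 1.0),
    "alpha_l": (0.0, 1.0),
    "beta": (0.0, 10.0),
    "kappa": (0.0, 1.0),
    "theta": None,
}


@dataclass(frozen=True)
class ModelSpec:
    """A member of the model bank.

    Parameters
    ----------
    name:
        Canonical label (``"M0"``, ``"M1-1"``, ... ``"M4-2"``).
    family:
        Comparison family used for model selection: ``"none"`` (M0),
        ``"reward"`` (M1), ``"belief"`` (M2), ``"belief2"`` (M3) or
        ``"pref_only"`` (M4).
    update_family:
        Which state machinery the model runs on: ``"reward"`` or
        ``"belief"``.  M3 runs on belief state; M0/M4-1 on (frozen) reward
        state; M4-2 on (frozen) belief state.
    n_alphas:
        0, 1 or 2 learning rates (2 = separate ``alpha_h``/``alpha_l`` per
        opponent).
    has_theta:
        Whether the swerve-preference bias enters the choice rule.
    has_kappa:
        Whether the second-order influence term enters the belief update.
    frozen:
        If true the state is never updated (non-learning baselines).
    """

    name: str
    family: str
    update_family: str
    n_alphas: int
    has_theta: bool = False
    has_kappa: bool = False
    frozen: bool = False

    @property
    def free_params(self) -> tuple[str, ...]:
        names: list[str] = []
        if self.n_alphas == 1:
            names.append("alpha")
        elif self.n_alphas == 2:
            names.extend(["alpha_h", "alpha_l"])
        names.append("beta")
        if self.has_kappa:
            names.append("kappa")
        if self.has_theta:
            names.append("theta")
        return tuple(names)


def _bank() -> dict[str, ModelSpec]:
    bank = {
        "M0": ModelSpec("M0", "none", "reward", 0, frozen=True),
        "M1-1": ModelSpec("M1-1", "reward", "reward", 1),
        "M1-2": ModelSpec("M1-2", "reward", "reward", 2),
        "M1-3": ModelSpec("M1-3", "reward", "reward", 2, has_theta=True),
        "M2-1": ModelSpec("M2-1", "belief", "belief", 1),
        "M2-2": ModelSpec("M2-2", "belief", "belief", 2),
        "M2-3": ModelSpec("M2-3", "belief", "belief", 2, has_theta=True),
        "M3-1": ModelSpec("M3-1", "belief2", "belief", 1, has_kappa=True),
        "M3-2": ModelSpec("M3-2", "belief2", "belief", 2, has_kappa=True),
        "M3-3": ModelSpec("M3-3", "belief2", "belief", 2, has_theta=True, has_kappa=True),
        "M4-1": ModelSpec("M4-1", "pref_only", "reward", 0, has_theta=True, frozen=True),
        "M4-2": ModelSpec("M4-2", "pref_only", "belief", 0, has_theta=True, frozen=True),
    }
    return bank


#: The twelve-model bank, addressable by canonical name.
MODEL_BANK: dict[str, ModelSpec] = _bank()


def get_model(name: str) -> ModelSpec:
    try:
        return MODEL_BANK[name]
    except KeyError:
        raise KeyError(
            f"unknown model {name!r}; known models: {', '.join(MODEL_BANK)}"
        ) from None


@dataclass
class ParamSet:
    """Natural-scale parameter values for one model.

    Only the fields named by ``ModelSpec.free_params`` are read; the rest
    may stay ``None``.
    """

    alpha: Optional[float] = None
    alpha_h: Optional[float] = None
    alpha_l: Optional[float] = None
    beta: Optional[float] = None
    kappa: Optional[float] = None
    theta: Optional[float] = None

    @classmethod
    def from_dict(cls, values: dict[str, float]) -> "ParamSet":
        return cls(**{k: float(v) for k, v in values.items()})

    def as_dict(self, model: ModelSpec) -> dict[str, float]:
        return {name: getattr(self, name) for name in model.free_params}

    def validate(self, model: ModelSpec) -> None:
        for name in model.free_params:
            value = getattr(self, name)
            if value is None:
                raise ValueError(f"{model.name} requires parameter {name!r}")
            bounds = PARAM_BOUNDS[name]
            if bounds is not None and not (bounds[0] <= value <= bounds[1]):
                raise ValueError(
                    f"{name}={value} outside declared range {bounds} for {model.name}"
                )

    def alpha_for(self, model: ModelSpec, opponent: str) -> float:
        """Learning rate applying to a trial against ``opponent``."""
        if model.n_alphas == 2:
            return self.alpha_h if opponent == "HCO" else self.alpha_l
        if model.n_alphas == 1:
            return self.alpha
        return 0.0


@dataclass
class LearnerState:
    """Per-opponent action values and beliefs carried across trials.

    ``v[o, a]`` is the value of action ``a`` (0 = Go straight, 1 = Swerve)
    against opponent index ``o``; ``p[o]`` is the believed probability that
    opponent ``o`` swerves.
    """

    v: np.ndarray = field(default_factory=lambda: np.zeros((2, 2)))
    p: np.ndarray = field(default_factory=lambda: np.full(2, 0.5))

    def copy(self) -> "LearnerState":
        return LearnerState(v=self.v.copy(), p=self.p.copy())


def opponent_index(opponent: str) -> int:
    try:
        return OPPONENTS.index(opponent)
    except ValueError:
        raise ValueError(f"unknown opponent label {opponent!r}") from None


def belief_ev_coeffs(matrix) -> tuple[float, float]:
    """Affine coefficients ``(A, B)`` of the belief-family value difference.

    From the payoff matrix, ``V_swerve - V_go = A + B * p`` with
    ``A = sg - gg`` and ``B = (ss - sg) - (gs - gg)``.  Under the Study-1
    matrix (3, 1, 1, 0) this is exactly ``1 - 3p``.
    """
    A = matrix.sg - matrix.gg
    B = (matrix.ss - matrix.sg) - (matrix.gs - matrix.gg)
    return float(A), float(B)


def init_state(model: ModelSpec, matrix=None) -> LearnerState:
    """Initial learner state: zero action values, beliefs at 0.5."""
    return LearnerState()


def reward_update(
    state: LearnerState, opponent: str, choice: int, reward: float, alpha: float
) -> LearnerState:
    """Delta-rule update of the chosen action's value (in place).

    Only the chosen action's value for the current opponent moves toward the
    received reward by fraction ``alpha``; the unchosen action is frozen.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    o = opponent_index(opponent)
    state.v[o, choice] += alpha * (reward - state.v[o, choice])
    return state


def belief_update(state: LearnerState, opponent: str, o_t: int, alpha: float) -> LearnerState:
    """Fictitious-play update of the opponent's swerve probability (in place)."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    o = opponent_index(opponent)
    state.p[o] += alpha * (o_t - state.p[o])
    return state


def second_order_q(p: float, beta: float, matrix) -> float:
    """Opponent's inferred probability that the participant swerves.

    Inverts the participant's own softmax: returns the ``q`` solving
    ``beta * (A + B * q) = logit(p)`` for the configured payoff matrix.
    Under the Study-1 matrix this reduces to the closed form
    ``q = 1/3 + log((1 - p) / p) / (3 * beta)``.
    """
    if beta <= 0:
        raise ValueError("second-order inference requires beta > 0")
    A, B = belief_ev_coeffs(matrix)
    if B == 0:
        raise ValueError("degenerate payoff matrix: belief slope B = 0")
    pc = min(max(p, BELIEF_EPS), 1.0 - BELIEF_EPS)
    return (math.log(pc / (1.0 - pc)) / beta - A) / B


def belief2_update(
    state: LearnerState,
    opponent: str,
    o_t: int,
    q_t: int,
    alpha: float,
    kappa: float,
    beta: float,
    matrix,
) -> LearnerState:
    """Second-order belief update (in place).

    ``p' = p + alpha * (O_t - p) + kappa * (Q_t - q_t_hat)`` where
    ``q_t_hat`` is :func:`second_order_q` of the current belief; the result
    is clipped into ``[eps, 1 - eps]``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha={alpha} outside [0, 1]")
    if not 0.0 <= kappa <= 1.0:
        raise ValueError(f"kappa={kappa} outside [0, 1]")
    o = opponent_index(opponent)
    q_hat = second_order_q(state.p[o], beta, matrix)
    p_new = state.p[o] + alpha * (o_t - state.p[o]) + kappa * (q_t - q_hat)
    state.p[o] = min(max(p_new, BELIEF_EPS), 1.0 - BELIEF_EPS)
    return state


def expected_value(model: ModelSpec, state: LearnerState, matrix, opponent: str) -> float:
    """Value difference favouring Swerve for the current opponent."""
    o = opponent_index(opponent)
    if model.update_family == "reward":
        return float(state.v[o, SWERVE] - state.v[o, GO_STRAIGHT])
    A, B = belief_ev_coeffs(matrix)
    return A + B * float(state.p[o])


def _sigmoid(x: float) -> float:
    # numerically stable logistic
    if x >= 0:
        return 1.0 / (1.0 + math.exp(-x))
    e = math.exp(x)
    return e / (1.0 + e)


def choice_prob(model: ModelSpec, ev: float, beta: float, theta: float = 0.0) -> float:
    """Probability of choosing Swerve: logistic of ``beta*EV`` (+ ``theta``)."""
    x = beta * ev
    if model.has_theta:
        x += theta
    return _sigmoid(x)


def _log_choice_prob(x: float, choice: int) -> float:
    # log sigma(x) if choice == SWERVE else log(1 - sigma(x)), stable
    if choice == SWERVE:
        return -math.log1p(math.exp(-x)) if x >= 0 else x - math.log1p(math.exp(x))
    return -x - math.log1p(math.exp(-x)) if x >= 0 else -math.log1p(math.exp(x))


def session_loglik(
    model: ModelSpec,
    params: ParamSet,
    session,
    matrix=None,
    reward_scale: Optional[float] = None,
) -> tuple[float, np.ndarray]:
    """Log-likelihood of a session's observed choices under one model.

    Replays the session: at each trial the swerve probability is computed
    from the current state, the observed choice scored, and the state then
    updated with the observed (choice, opponent choice, reward).  Models
    with two learning rates pick ``alpha_h`` or ``alpha_l`` by the trial's
    opponent.  Rewards are divided by ``reward_scale`` (from the session's
    design unless overridden) before entering the delta rule, keeping the
    inverse temperature comparable across payoff scales.

    Returns the total log-likelihood and the per-trial pointwise vector.
    """
    params.validate(model)
    if matrix is None:
        matrix = session.design.payoff
    if reward_scale is None:
        reward_scale = getattr(session.design, "reward_scale", 1.0)
    theta = params.theta if model.has_theta else 0.0
    beta = params.beta

    state = init_state(model, matrix)
    pointwise = np.empty(len(session.trials))
    for t, trial in enumerate(session.trials):
        ev = expected_value(model, state, matrix, trial.opponent)
        x = beta * ev + (theta if model.has_theta else 0.0)
        pointwise[t] = _log_choice_prob(x, trial.choice)
        if not model.frozen:
            alpha = params.alpha_for(model, trial.opponent)
            if model.update_family == "reward":
                reward_update(
                    state, trial.opponent, trial.choice, trial.reward / reward_scale, alpha
                )
            elif model.has_kappa:
                belief2_update(
                    state,
                    trial.opponent,
                    trial.opponent_choice,
                    trial.choice,
                    alpha,
                    params.kappa,
                    beta,
                    matrix,
                )
            else:
                belief_update(state, trial.opponent, trial.opponent_choice, alpha)
    return float(pointwise.sum()), pointwise
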