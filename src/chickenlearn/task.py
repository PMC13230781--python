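"""Chicken-game environment and synthetic-cohort generation.

Two players drive toward each other and each chooses *Swerve* (safe,
cooperative) or *Go straight* (competitive).  The payoff matrix makes
unilateral Go straight the best outcome and mutual Go straight the worst.
Participants face two pre-programmed opponents: a high-competitive opponent
(HCO) who goes straight with probability 0.70 and a low-competitive
opponent (LCO) with probability 0.30, independently across trials.

Two study designs are provided:

* ``study1`` — simplified matrix without losses (gs=3, ss=sg=1, gg=0, in
  "flowers"); each opponent appears in four contiguous blocks of 10 trials
  (80 trials total), with opponent order counterbalanced across subjects.
* ``study2`` — full matrix with losses (default 30, 10, -10, -30 points,
  gg = -30); 50 trials per opponent interleaved in random order (100
  trials), analysed in bins of 20 consecutive trials.

Cohorts of synthetic participants can be generated from any model in the
bank, with per-subject parameters drawn from group-level normal
distributions on the unbounded scale and mapped into their bounds by the
same probit transform used during inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .models import (
    GO_STRAIGHT,
    OPPONENTS,
    PARAM_BOUNDS,
    SWERVE,
    LearnerState,
    ModelSpec,
    ParamSet,
    belief2_update,
    belief_update,
    choice_prob,
    expected_value,
    init_state,
    reward_update,
)

__all__ = [
    "PayoffMatrix",
    "OpponentPolicy",
    "DesignSpec",
    "TrialRecord",
    "Session",
    "CohortSpec",
    "STUDY1_PAYOFF",
    "STUDY2_PAYOFF",
    "HCO",
    "LCO",
    "make_design",
    "opponent_schedule",
    "sample_opponent_choice",
    "payoff",
    "simulate_session",
    "generate_cohort",
    "block_cooperation_rates",
    "raw_group_mean",
]


@dataclass(frozen=True)
class PayoffMatrix:
    """Symmetric 2x2 payoffs from the participant's perspective.

    ``ss``: both swerve; ``sg``: self swerves, opponent goes straight;
    ``gs``: self goes straight, opponent swerves; ``gg``: both go straight.
    """

    ss: float
    sg: float
    gs: float
    gg: float

    def payoff(self, choice: int, opponent_choice: int) -> float:
        if choice == SWERVE:
            return self.ss if opponent_choice == SWERVE else self.sg
        return self.gs if opponent_choice == SWERVE else self.gg


#: Study-1 simplified matrix (flowers): GS > SS = SG > GG, no losses.
STUDY1_PAYOFF = PayoffMatrix(ss=1.0, sg=1.0, gs=3.0, gg=0.0)
#: Study-2 full matrix (points): GS > SS > SG > GG with a crash cost of 30.
STUDY2_PAYOFF = PayoffMatrix(ss=10.0, sg=-10.0, gs=30.0, gg=-30.0)


@dataclass(frozen=True)
class OpponentPolicy:
    label: str
    p_go_straight: float

    def __post_init__(self):
        if not 0.0 <= self.p_go_straight <= 1.0:
            raise ValueError("p_go_straight must lie in [0, 1]")


HCO = OpponentPolicy("HCO", 0.70)
LCO = OpponentPolicy("LCO", 0.30)


@dataclass(frozen=True)
class DesignSpec:
    """Session structure of one study.

    ``n_blocks`` and ``trials_per_block`` describe the whole session
    (study1: 8 blocks of 10; study2: 5 analysis bins of 20).  ``reward_scale``
    divides payoffs before they enter the reward-family delta rule so the
    inverse temperature stays on a comparable scale across studies.
    """

    study: str
    n_blocks: int
    trials_per_block: int
    schedule: str  # "blocked_counterbalanced" | "interleaved_random"
    trials_per_opponent: int
    payoff: PayoffMatrix
    reward_scale: float = 1.0
    policies: tuple[OpponentPolicy, OpponentPolicy] = (HCO, LCO)

    @property
    def total_trials(self) -> int:
        return self.n_blocks * self.trials_per_block

    def policy(self, label: str) -> OpponentPolicy:
        for pol in self.policies:
            if pol.label == label:
                return pol
        raise ValueError(f"unknown opponent label {label!r}")


@dataclass(frozen=True)
class TrialRecord:
    subject_id: str
    trial_index: int  # 1-based
    block: int  # 1-based
    opponent: str  # "HCO" | "LCO"
    choice: int  # 1 = Swerve, 0 = Go straight
    opponent_choice: int
    reward: float


@dataclass
class Session:
    """One subject's full trial sequence."""

    subject_id: str
    group: str
    design: DesignSpec
    trials: list[TrialRecord]

    def __len__(self) -> int:
        return len(self.trials)

    def arrays(self) -> dict[str, np.ndarray]:
        """Columnar view used by the fitting kernels."""
        return {
            "choice": np.array([t.choice for t in self.trials], dtype=np.int64),
            "opponent_choice": np.array(
                [t.opponent_choice for t in self.trials], dtype=np.int64
            ),
            "opponent_index": np.array(
                [OPPONENTS.index(t.opponent) for t in self.trials], dtype=np.int64
            ),
            "reward": np.array([t.reward for t in self.trials], dtype=np.float64),
        }


def make_design(study: str) -> DesignSpec:
    """Preset design for ``"study1"`` or ``"study2"``."""
    if study == "study1":
        return DesignSpec(
            study="study1",
            n_blocks=8,
            trials_per_block=10,
            schedule="blocked_counterbalanced",
            trials_per_opponent=40,
            payoff=STUDY1_PAYOFF,
            reward_scale=1.0,
        )
    if study == "study2":
        return DesignSpec(
            study="study2",
            n_blocks=5,
            trials_per_block=20,
            schedule="interleaved_random",
            trials_per_opponent=50,
            payoff=STUDY2_PAYOFF,
            reward_scale=10.0,
        )
    raise ValueError(f"unknown study {study!r}; expected 'study1' or 'study2'")


def design_from_config(config: dict) -> DesignSpec:
    """Build a design from a (YAML/JSON-loaded) mapping.

    Starts from the ``study`` preset and overrides any of ``payoff``
    (mapping with ss/sg/gs/gg), ``policies`` (label -> p_go_straight),
    ``n_blocks``, ``trials_per_block``, ``trials_per_opponent`` and
    ``reward_scale``.
    """
    design = make_design(config.get("study", "study1"))
    overrides: dict = {}
    if "payoff" in config:
        overrides["payoff"] = PayoffMatrix(**{k: float(v) for k, v in config["payoff"].items()})
    if "policies" in config:
        overrides["policies"] = tuple(
            OpponentPolicy(label, float(p)) for label, p in config["policies"].items()
        )
    for key in ("n_blocks", "trials_per_block", "trials_per_opponent", "reward_scale"):
        if key in config:
            overrides[key] = config[key]
    return replace(design, **overrides)


def opponent_schedule(
    design: DesignSpec, seed: Optional[int] = None, hco_first: bool = True
) -> list[str]:
    """Ordered opponent labels for one session.

    Blocked designs alternate opponents in contiguous halves honouring the
    counterbalance flag; interleaved designs are a uniformly random
    permutation of the fixed 50/50 multiset, determined entirely by the
    seed.
    """
    if design.schedule == "blocked_counterbalanced":
        first, second = ("HCO", "LCO") if hco_first else ("LCO", "HCO")
        half = design.trials_per_opponent
        return [first] * half + [second] * half
    if design.schedule == "interleaved_random":
        rng = np.random.default_rng(seed)
        labels = np.array(
            ["HCO"] * design.trials_per_opponent + ["LCO"] * design.trials_per_opponent
        )
        rng.shuffle(labels)
        return labels.tolist()
    raise ValueError(f"unknown schedule {design.schedule!r}")


def sample_opponent_choice(policy: OpponentPolicy, rng: np.random.Generator) -> int:
    """One Bernoulli draw from the opponent's policy."""
    return GO_STRAIGHT if rng.random() < policy.p_go_straight else SWERVE


def payoff(matrix: PayoffMatrix, choice: int, opponent_choice: int) -> float:
    return matrix.payoff(choice, opponent_choice)


def simulate_session(
    model: ModelSpec,
    params: ParamSet,
    design: DesignSpec,
    seed: Optional[int] = None,
    subject_id: str = "s000",
    group: str = "",
    hco_first: bool = True,
    opponent_choices: Optional[Sequence[int]] = None,
    schedule: Optional[Sequence[str]] = None,
) -> Session:
    """Forward-simulate one agent through a full session.

    Each trial: the opponent's choice is drawn from that trial's policy
    (or taken from ``opponent_choices`` when replaying a recorded session),
    the agent's swerve probability is computed from its current state, the
    agent's choice sampled, the payoff assigned, and the state updated by
    the model's learning rule.
    """
    params.validate(model)
    rng = np.random.default_rng(seed)
    if schedule is None:
        schedule = opponent_schedule(design, seed=rng.integers(2**31), hco_first=hco_first)
    if len(schedule) != design.total_trials:
        raise ValueError("schedule length does not match design")
    if opponent_choices is not None and len(opponent_choices) != design.total_trials:
        raise ValueError("opponent_choices length does not match design")

    matrix = design.payoff
    theta = params.theta if model.has_theta else 0.0
    state = init_state(model, matrix)
    trials: list[TrialRecord] = []
    for t, opp in enumerate(schedule):
        if opponent_choices is not None:
            opp_choice = int(opponent_choices[t])
        else:
            opp_choice = sample_opponent_choice(design.policy(opp), rng)
        ev = expected_value(model, state, matrix, opp)
        p_swerve = choice_prob(model, ev, params.beta, theta)
        choice = SWERVE if rng.random() < p_swerve else GO_STRAIGHT
        reward = matrix.payoff(choice, opp_choice)
        trials.append(
            TrialRecord(
                subject_id=subject_id,
                trial_index=t + 1,
                block=t // design.trials_per_block + 1,
                opponent=opp,
                choice=choice,
                opponent_choice=opp_choice,
                reward=reward,
            )
        )
        if not model.frozen:
            alpha = params.alpha_for(model, opp)
            if model.update_family == "reward":
                reward_update(state, opp, choice, reward / design.reward_scale, alpha)
            elif model.has_kappa:
                belief2_update(
                    state, opp, opp_choice, choice, alpha, params.kappa, params.beta, matrix
                )
            else:
                belief_update(state, opp, opp_choice, alpha)
    return Session(subject_id=subject_id, group=group, design=design, trials=trials)


def raw_group_mean(param: str, natural_value: float) -> float:
    """Unbounded-scale group mean whose probit image is ``natural_value``.

    Inverse of the bound transform used in inference; identity for the
    unbounded preference parameter.
    """
    bounds = PARAM_BOUNDS[param]
    if bounds is None:
        return float(natural_value)
    lo, hi = bounds
    frac = (natural_value - lo) / (hi - lo)
    if not 0.0 < frac < 1.0:
        raise ValueError(f"{param}={natural_value} not strictly inside {bounds}")
    return float(ndtri(frac))


@dataclass
class CohortSpec:
    """Recipe for a synthetic cohort.

    ``group_means``/``group_sds`` are on the unbounded (raw) scale, one
    entry per free parameter of the generating model; subjects' raw values
    are drawn from those normals and mapped into bounds by the probit
    transform, mirroring the hierarchical prior.  Use
    :meth:`from_natural_means` to specify means on the natural scale.
    """

    n_subjects: int
    design: DesignSpec
    generating_model: ModelSpec
    group_means: dict[str, float]
    group_sds: dict[str, float]
    seed: int = 0
    group: str = ""

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        for name in self.generating_model.free_params:
            if name not in self.group_means:
                raise ValueError(f"missing group mean for {name!r}")
            if self.group_sds.get(name, 0.0) < 0:
                raise ValueError(f"negative sd for {name!r}")

    @classmethod
    def from_natural_means(
        cls,
        n_subjects: int,
        design: DesignSpec,
        generating_model: ModelSpec,
        natural_means: dict[str, float],
        raw_sds: Optional[dict[str, float]] = None,
        seed: int = 0,
        group: str = "",
    ) -> "CohortSpec":
        raw_sds = raw_sds or {}
        means = {k: raw_group_mean(k, v) for k, v in natural_means.items()}
        sds = {k: raw_sds.get(k, 0.25) for k in natural_means}
        return cls(n_subjects, design, generating_model, means, sds, seed, group)


def _transform(param: str, raw: np.ndarray) -> np.ndarray:
    bounds = PARAM_BOUNDS[param]
    if bounds is None:
        return raw
    lo, hi = bounds
    return lo + (hi - lo) * ndtr(raw)


def generate_cohort(spec: CohortSpec) -> tuple[list[Session], pd.DataFrame]:
    """Simulate a cohort; returns sessions plus the ground-truth table.

    The truth table holds each subject's natural-scale parameters (for
    recovery analyses).  Study-1 cohorts alternate HCO-first/LCO-first
    across subjects; the seed fully determines the output.
    """
    rng = np.random.default_rng(spec.seed)
    model = spec.generating_model
    names = model.free_params
    rows = []
    sessions = []
    for i in range(spec.n_subjects):
        sid = f"s{i:03d}"
        raw = {
            k: rng.normal(spec.group_means[k], spec.group_sds.get(k, 0.0)) for k in names
        }
        natural = {k: float(_transform(k, np.asarray(raw[k]))) for k in names}
        params = ParamSet.from_dict(natural)
        session = simulate_session(
            model,
            params,
            spec.design,
            seed=int(rng.integers(2**31)),
            subject_id=sid,
            group=spec.group,
            hco_first=(i % 2 == 0),
        )
        sessions.append(session)
        rows.append({"subject_id": sid, **natural})
    truth = pd.DataFrame(rows).set_index("subject_id")
    return sessions, truth


def block_cooperation_rates(sessions: Sequence[Session]) -> pd.DataFrame:
    """Per (subject, opponent, block) proportion of Swerve choices.

    Blocks with no trials for an opponent appear with a missing rate, so
    blocked and interleaved designs produce comparable tables.
    """
    if not sessions:
        raise ValueError("no sessions given")
    records = [
        {
            "subject_id": s.subject_id,
            "opponent": t.opponent,
            "block": t.block,
            "choice": t.choice,
        }
        for s in sessions
        for t in s.trials
    ]
    df = pd.DataFrame(records)
    rates = (
        df.groupby(["subject_id", "opponent", "block"])["choice"].mean().rename("swerve_rate")
    )
    blocks = sorted(df["block"].unique())
    full_index = pd.MultiIndex.from_product(
        [sorted(df["subject_id"].unique()), list(OPPONENTS), blocks],
        names=["subject_id", "opponent", "block"],
    )
    return rates.reindex(full_index).reset_index()
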