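"""Trial CSV reading/writing and configuration plumbing.

The canonical trial table is long-format, one row per subject x trial, with
columns ``subject_id, group, trial_index, block, opponent, choice,
opponent_choice, reward``; choices are spelled ``swerve``/``go_straight``
and opponents ``HCO``/``LCO``.  Foreign exports with different column names
can be loaded through a column-mapping dict.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from .models import GO_STRAIGHT, OPPONENTS, SWERVE
from .task import DesignSpec, Session, TrialRecord

logger = logging.getLogger(__name__)

__all__ = [
    "TrialValidationError",
    "ReadReport",
    "read_trials",
    "read_trials_report",
    "write_trials",
    "load_config",
]

_COLUMNS = [
    "subject_id",
    "group",
    "trial_index",
    "block",
    "opponent",
    "choice",
    "opponent_choice",
    "reward",
]
_CHOICE_LABELS = {SWERVE: "swerve", GO_STRAIGHT: "go_straight"}
_CHOICE_CODES = {"swerve": SWERVE, "go_straight": GO_STRAIGHT}


class TrialValidationError(ValueError):
    """Raised when a trial table violates the schema or payoff contract."""


@dataclass
class ReadReport:
    n_rows: int = 0
    n_dropped_missing_choice: int = 0
    reward_mismatch_rows: list[int] = field(default_factory=list)


def write_trials(sessions: Sequence[Session], path) -> None:
    rows = [
        {
            "subject_id": t.subject_id,
            "group": s.group,
            "trial_index": t.trial_index,
            "block": t.block,
            "opponent": t.opponent,
            "choice": _CHOICE_LABELS[t.choice],
            "opponent_choice": _CHOICE_LABELS[t.opponent_choice],
            "reward": t.reward,
        }
        for s in sessions
        for t in s.trials
    ]
    pd.DataFrame(rows, columns=_COLUMNS).to_csv(path, index=False)


def read_trials_report(
    path,
    design: Optional[DesignSpec] = None,
    column_map: Optional[dict[str, str]] = None,
    strict: bool = True,
) -> tuple[list[Session], ReadReport]:
    """Read and validate a trial CSV; returns sessions plus a read report.

    Rows with a missing choice (timeouts in real data) are dropped and
    counted.  When a design is given, the reward column is cross-checked
    against the payoff matrix; mismatching rows raise (``strict``) or are
    reported.
    """
    df = pd.read_csv(path)
    if column_map:
        df = df.rename(columns=column_map)
    missing_cols = [c for c in _COLUMNS if c not in df.columns]
    if missing_cols:
        raise TrialValidationError(f"missing columns: {missing_cols}")

    report = ReadReport(n_rows=len(df))
    missing_choice = df["choice"].isna() | (df["choice"].astype(str).str.strip() == "")
    if missing_choice.any():
        report.n_dropped_missing_choice = int(missing_choice.sum())
        logger.info("dropped %d rows with missing choice", report.n_dropped_missing_choice)
        df = df[~missing_choice]

    for col in ("choice", "opponent_choice"):
        bad = ~df[col].isin(_CHOICE_CODES)
        if bad.any():
            raise TrialValidationError(
                f"unknown {col} labels: {sorted(df.loc[bad, col].unique())}"
            )
    bad_opp = ~df["opponent"].isin(OPPONENTS)
    if bad_opp.any():
        raise TrialValidationError(
            f"unknown opponent labels: {sorted(df.loc[bad_opp, 'opponent'].unique())}"
        )

    if design is not None:
        expected = [
            design.payoff.payoff(_CHOICE_CODES[c], _CHOICE_CODES[o])
            for c, o in zip(df["choice"], df["opponent_choice"])
        ]
        mismatch = ~np.isclose(df["reward"].to_numpy(float), np.asarray(expected))
        if mismatch.any():
            report.reward_mismatch_rows = df.index[mismatch].tolist()
            msg = (
                f"{mismatch.sum()} rows with reward inconsistent with the payoff "
                f"matrix (rows {report.reward_mismatch_rows[:10]}...)"
            )
            if strict:
                raise TrialValidationError(msg)
            logger.warning(msg)

    sessions = []
    for sid, sub in df.groupby("subject_id", sort=False):
        sub = sub.sort_values("trial_index")
        idx = sub["trial_index"].to_numpy()
        if not np.all(np.diff(idx) > 0):
            raise TrialValidationError(f"non-monotone trial indices for subject {sid}")
        trials = [
            TrialRecord(
                subject_id=str(sid),
                trial_index=int(r.trial_index),
                block=int(r.block),
                opponent=str(r.opponent),
                choice=_CHOICE_CODES[r.choice],
                opponent_choice=_CHOICE_CODES[r.opponent_choice],
                reward=float(r.reward),
            )
            for r in sub.itertuples()
        ]
        group = str(sub["group"].iloc[0]) if not sub["group"].isna().all() else ""
        sessions.append(Session(subject_id=str(sid), group=group, design=design, trials=trials))
    return sessions, report


def read_trials(path, design: Optional[DesignSpec] = None, **kwargs) -> list[Session]:
    sessions, _ = read_trials_report(path, design=design, **kwargs)
    return sessions


def load_config(path) -> dict:
    """Load a YAML or JSON run configuration."""
    text = Path(path).read_text()
    return yaml.safe_load(text)
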