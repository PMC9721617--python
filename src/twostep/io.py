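"""Reading and writing the standard trial-table CSV and YAML configs."""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
import yaml

from .cohort import ARMS, SERUM_GROUPS, TRIAL_COLUMNS, CohortSpec
from .exceptions import ValidationError
from .task import PLANETS

log = logging.getLogger("twostep")

REQUIRED_COLUMNS = ["subject_id", "session", "trial", "first_state", "action",
                    "planet", "reward", "drug"]


def read_trials(path, reward_bounds=(-4, 5)) -> pd.DataFrame:
    """Load and validate a trial table.

    Structural violations (missing columns, unknown labels, non-integer or
    out-of-bounds rewards) raise :class:`ValidationError` naming the
    offending rows (1-based, excluding the header).  Rows with missing
    values are dropped with a logged count.
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing columns {missing}", offenders=missing)
    n0 = len(df)
    df = df.dropna(subset=REQUIRED_COLUMNS)
    if len(df) < n0:
        log.warning("dropped %d incomplete rows from %s", n0 - len(df), path)

    problems = []

    def check(mask, message):
        if mask.any():
            rows = (df.index[mask] + 2).tolist()[:20]
            problems.append(f"{message} (rows {rows})")

    check(~df["drug"].isin(ARMS), "unknown drug label "
          f"{sorted(set(df['drug']) - set(ARMS))}")
    if "serum_group" in df.columns:
        ser = df["serum_group"].fillna("NA")
        check(~ser.isin(SERUM_GROUPS), "unknown serum_group label")
    check(~df["planet"].isin(PLANETS), "unknown planet label")
    check(~df["session"].isin((1, 2)), "session must be 1 or 2")
    check(~df["first_state"].isin((1, 2)), "first_state must be 1 or 2")
    check(~df["action"].isin((1, 2)), "action must be 1 or 2")
    reward = pd.to_numeric(df["reward"], errors="coerce")
    check(reward.isna() | (reward != reward.round()), "non-integer reward")
    lo, hi = reward_bounds
    check((reward < lo) | (reward > hi), f"reward outside [{lo}, {hi}]")
    if problems:
        raise ValidationError("invalid trial table: " + "; ".join(problems),
                              offenders=problems)
    df = df.copy()
    for col in ("session", "trial", "first_state", "action", "reward"):
        df[col] = df[col].astype(int)
    if "serum_group" not in df.columns:
        df["serum_group"] = "NA"
    df["serum_group"] = df["serum_group"].fillna("NA")
    return df.reset_index(drop=True)


def write_trials(df: pd.DataFrame, path) -> None:
    cols = [c for c in TRIAL_COLUMNS if c in df.columns]
    df[cols].to_csv(path, index=False)


def spec_to_yaml(spec: CohortSpec, path) -> None:
    payload = {
        "n_per_arm": dict(spec.n_per_arm),
        "model_id": spec.model_id,
        "hyper_means": [float(x) for x in spec.hyper_means],
        "hyper_sds": [float(x) for x in spec.hyper_sds],
        "correlation": np.asarray(spec.correlation).tolist(),
        "drug_effects": {f"{arm}:{name}": float(v)
                         for (arm, name), v in spec.drug_effects.items()},
        "serum_effects": {k: float(v) for k, v in spec.serum_effects.items()},
        "serum_measured": float(spec.serum_measured),
        "serum_split": float(spec.serum_split),
        "n_trials": int(spec.n_trials),
        "n_sessions": int(spec.n_sessions),
        "master_seed": int(spec.master_seed),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def spec_from_yaml(path) -> CohortSpec:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    drug_effects = {
        tuple(key.split(":", 1)): float(v)
        for key, v in (payload.pop("drug_effects", {}) or {}).items()
    }
    corr = payload.pop("correlation", None)
    return CohortSpec(
        drug_effects=drug_effects,
        correlation=np.asarray(corr) if corr is not None else None,
        **{k: (tuple(v) if isinstance(v, list) else v)
           for k, v in payload.items()},
    )


def task_config_to_yaml(config, path) -> None:
    """Serialize a TaskConfig (all seeds and schedules explicit)."""
    payload = {
        "n_trials": int(config.n_trials),
        "reward_bounds": [int(b) for b in config.reward_bounds],
        "drift_levels": [float(x) for x in config.drift_levels],
        "drift_schedule": [float(x) for x in config.drift_schedule],
        "transition_map": [list(row) for row in config.transition_map],
        "first_state_sequence": [int(s) for s in config.first_state_sequence],
        "points_to_cents": float(config.points_to_cents),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def task_config_from_yaml(path):
    from .task import TaskConfig

    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return TaskConfig(
        n_trials=payload["n_trials"],
        reward_bounds=tuple(payload["reward_bounds"]),
        drift_levels=tuple(payload["drift_levels"]),
        drift_schedule=tuple(payload["drift_schedule"]),
        transition_map=tuple(tuple(r) for r in payload["transition_map"]),
        first_state_sequence=tuple(payload["first_state_sequence"]),
        points_to_cents=payload["points_to_cents"],
    )
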