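"""Behavior-log CSV I/O, run configuration, and report writing.

The interchange format for one session is a CSV with header
``subject,block,trial,stimulus,action,outcome,rt,i_processed,entropy,system``;
missing diagnostics are empty fields.  Reports are JSON with sorted keys so
identical inputs produce byte-identical files.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .fitting import MODEL_SPECS, validate_params
from .task import BehaviorLog, TaskConfig, TrialRecord

__all__ = [
    "read_behavior_log",
    "write_behavior_log",
    "load_config",
    "write_report",
]

REQUIRED_COLUMNS = ("subject", "block", "trial", "stimulus", "action", "outcome")
ALL_COLUMNS = REQUIRED_COLUMNS + ("rt", "i_processed", "entropy", "system")


def write_behavior_log(log: BehaviorLog, path) -> None:
    df = log.to_frame()
    df.to_csv(path, index=False, float_format="%.10g")


def read_behavior_log(path, config: TaskConfig | None = None) -> BehaviorLog:
    """Parse and type-check a behavior-log CSV.

    Trial ordering and stimulus balance are enforced; rows with outcomes
    outside {0,1} or out-of-range action ids raise with the offending row.
    A missing/empty rt column loads with RTs absent (choice-only fitting).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    n_stimuli = int(df["stimulus"].max()) + 1
    n_actions = max(int(df["action"].max()) + 1, 5)
    n_blocks = int(df["block"].max()) + 1
    trials_per_block = int((df["block"] == 0).sum())
    if config is None:
        req = (1, 3, 4) if n_stimuli == 3 else tuple([1] * n_stimuli)
        config = TaskConfig(
            n_stimuli=n_stimuli,
            n_actions=n_actions,
            trials_per_block=trials_per_block,
            n_blocks=n_blocks,
            error_requirements=req,
        )
    trials = []
    for idx, row in df.iterrows():
        outcome = int(row["outcome"])
        if outcome not in (0, 1):
            raise ValueError(f"{path}: row {idx}: outcome {outcome} not in {{0,1}}")
        action = int(row["action"])
        if not 0 <= action < config.n_actions:
            raise ValueError(f"{path}: row {idx}: action {action} out of range")
        rt = row.get("rt", np.nan)
        ip = row.get("i_processed", np.nan)
        ent = row.get("entropy", np.nan)
        sys_ = row.get("system", np.nan)
        trials.append(
            TrialRecord(
                block=int(row["block"]),
                trial=int(row["trial"]),
                stimulus=int(row["stimulus"]),
                action=action,
                outcome=outcome,
                rt=None if pd.isna(rt) else float(rt),
                i_processed=None if pd.isna(ip) else int(ip),
                entropy=None if pd.isna(ent) else float(ent),
                system=None if pd.isna(sys_) else str(sys_),
            )
        )
    log = BehaviorLog(subject=str(df["subject"].iloc[0]), config=config, trials=trials)
    log.validate()
    return log


def load_config(path) -> dict:
    """Load a YAML/JSON run configuration and validate model parameters."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    model = cfg.get("model", {})
    if "id" in model and "params" in model:
        if model["id"] not in MODEL_SPECS:
            raise ValueError(f"{path}: unknown model id {model['id']!r}")
        validate_params(model["id"], model["params"])
    task = cfg.get("task", {})
    if task:
        TaskConfig(**{k: tuple(v) if isinstance(v, list) else v for k, v in task.items()})
    return cfg


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating, float)):
        v = float(obj)
        return v if np.isfinite(v) else None
    if isinstance(obj, np.ndarray):
        return _jsonable(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="list"))
    if hasattr(obj, "__dataclass_fields__"):
        return _jsonable(asdict(obj))
    return obj


def write_report(results: dict, path) -> str:
    """Write a machine-readable JSON report (sorted keys, deterministic)."""
    payload = json.dumps(_jsonable(results), sort_keys=True, indent=2)
    path = Path(path)
    try:
        path.parent.mkdir(parents=True, exist_ok=True)
        path.write_text(payload + "\n")
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    return payload
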