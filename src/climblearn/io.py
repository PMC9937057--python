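"""Run configuration and plain-text artifact I/O.

All pipeline artifacts are CSV or JSON so every reported number can be
traced to (and regenerated from) an intermediate file with any toolchain.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import yaml

from .constants import (
    GROUPS,
    METRICS,
    TARGET_COLUMNS,
    ConfigurationError,
)
from .curves import MetricSeries
from .fluency import DEFAULT_V_THRESHOLD, Trajectory
from .predict import TwoStageConfig
from .synth import LatentPrior, ProtocolConfig, TransferLinkage

__all__ = [
    "RunConfig",
    "read_trial_scores",
    "read_transfer",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "write_json",
]

_SCORE_COLUMNS = ["participant", "group", "session", "trial", "global_index", "route"]


@dataclass(frozen=True)
class RunConfig:
    """Everything needed to reproduce one end-to-end synthetic run."""

    protocol: ProtocolConfig = field(default_factory=ProtocolConfig)
    prior: LatentPrior = field(default_factory=LatentPrior)
    linkage_preset: str = "vp2_advantage"  # or "null"
    point_rate: float = 0.0025
    block_rate: float = 0.25
    two_stage: TwoStageConfig = field(default_factory=TwoStageConfig)
    v_threshold: float = DEFAULT_V_THRESHOLD
    seed: int = 0
    out_dir: str | None = None
    n_replications: int = 1

    def linkage(self) -> TransferLinkage:
        if self.linkage_preset == "vp2_advantage":
            return TransferLinkage.vp2_advantage()
        if self.linkage_preset == "null":
            return TransferLinkage.null()
        raise ConfigurationError(f"unknown linkage preset: {self.linkage_preset!r}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["protocol"]["group_sizes"] = dict(self.protocol.group_sizes)
        return d

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        blob = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]

    @classmethod
    def from_dict(cls, d: Mapping) -> "RunConfig":
        d = dict(d)
        if "protocol" in d:
            d["protocol"] = ProtocolConfig(**d["protocol"])
        if "prior" in d:
            d["prior"] = LatentPrior(**d["prior"])
        if "two_stage" in d:
            d["two_stage"] = TwoStageConfig(**d["two_stage"])
        return cls(**d)

    @classmethod
    def from_file(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(data or {})


def read_trial_scores(path: str | Path) -> tuple[list[MetricSeries], dict[str, str]]:
    """Load long-format per-trial scores; empty cells are missing values.

    Validates the schema and reports offending row numbers: unknown group
    labels, duplicated (participant, global_index) pairs and non-numeric
    scores are parse errors.
    """
    frame = pd.read_csv(path)
    missing_cols = [c for c in _SCORE_COLUMNS + list(METRICS) if c not in frame.columns]
    if missing_cols:
        raise ValueError(f"{path}: missing required columns {missing_cols}")
    bad_group = ~frame["group"].isin(GROUPS)
    if bad_group.any():
        rows = (frame.index[bad_group] + 2).tolist()  # 1-based incl. header
        raise ValueError(f"{path}: unknown group label at rows {rows[:5]}")
    dup = frame.duplicated(subset=["participant", "global_index"])
    if dup.any():
        rows = (frame.index[dup] + 2).tolist()
        raise ValueError(f"{path}: duplicated (participant, global_index) at rows {rows[:5]}")
    for m in METRICS:
        coerced = pd.to_numeric(frame[m], errors="coerce")
        bad = coerced.isna() & frame[m].notna() & (frame[m].astype(str).str.strip() != "")
        if bad.any():
            rows = (frame.index[bad] + 2).tolist()
            raise ValueError(f"{path}: non-numeric {m} score at rows {rows[:5]}")
        frame[m] = coerced

    series: list[MetricSeries] = []
    groups: dict[str, str] = {}
    for pid, sub in frame.groupby("participant", sort=True):
        sub = sub.sort_values("global_index")
        groups[str(pid)] = str(sub["group"].iloc[0])
        t = sub["global_index"].to_numpy(dtype=float)
        for m in METRICS:
            series.append(MetricSeries(str(pid), m, t, sub[m].to_numpy(dtype=float)))
    return series, groups


def read_transfer(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = [c for c in ("participant", *TARGET_COLUMNS) if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return frame


def read_trajectory_csv(path: str | Path) -> Trajectory:
    """Trajectory CSV with (t, x, y) columns; a header row is detected."""
    first = Path(path).open().readline()
    try:
        float(first.split(",")[0])
        has_header = False
    except ValueError:
        has_header = True
    frame = pd.read_csv(path, header=0 if has_header else None)
    if frame.shape[1] < 3:
        raise ValueError(f"{path}: expected 3 columns (t, x, y)")
    arr = frame.to_numpy(dtype=float)
    return Trajectory(t=arr[:, 0], xy=arr[:, 1:3])


def write_trajectory_csv(traj: Trajectory, path: str | Path) -> None:
    pd.DataFrame({"t": traj.t, "x": traj.xy[:, 0], "y": traj.xy[:, 1]}).to_csv(
        path, index=False
    )


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return [_jsonable(v) for v in obj.tolist()]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def write_json(data, path: str | Path) -> None:
    Path(path).write_text(json.dumps(_jsonable(data), indent=2, sort_keys=True) + "\n")
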