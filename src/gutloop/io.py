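"""Run manifests and file writers (TSV trajectories, CSV metrics, JSON)."""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import SimConfig
from .scenarios import PHASE_NAMES, TrajectoryRecord

__all__ = [
    "RunManifest",
    "write_trajectory_tsv",
    "write_proportions_tsv",
    "write_metrics_csv",
]


@dataclass
class RunManifest:
    """Everything needed to re-run a simulation exactly: the fully resolved
    configuration, the seed, the code version, timing, and any warnings."""

    config: dict
    seed: int | None
    version: str = __version__
    started: str = ""
    finished: str = ""
    warnings: list = field(default_factory=list)

    @classmethod
    def for_run(cls, config: SimConfig, seed: int | None) -> "RunManifest":
        return cls(config=config.to_dict(), seed=seed)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunManifest":
        return cls(**json.loads(text))

    def write(self, path: str | Path) -> None:
        Path(path).write_text(self.to_json() + "\n")


def write_trajectory_tsv(record: TrajectoryRecord, path: str | Path) -> None:
    """Per-step behavior time series: step, phase label, b1."""
    labels = [PHASE_NAMES.get(int(p), str(int(p))) for p in record.phase]
    pd.DataFrame({
        "step": np.arange(record.b1.size),
        "phase": labels,
        "b1": record.b1,
    }).to_csv(path, sep="\t", index=False)


def write_proportions_tsv(record: TrajectoryRecord, path: str | Path) -> None:
    """Thinned per-strain proportions: one row per recorded step."""
    if record.proportions is None:
        raise ValueError("trajectory record carries no proportions")
    x = record.proportions
    df = pd.DataFrame(x, columns=[f"x{i + 1}" for i in range(x.shape[1])])
    df.insert(0, "step", np.arange(x.shape[0]) * record.thin)
    df.to_csv(path, sep="\t", index=False)


def write_metrics_csv(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)
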