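"""Dataset containers for the three observation modalities, with CSV I/O.

Count data: terminal cell counts per (condition, termination time,
replicate).  Event data: proliferation/death event counts in consecutive
time bins, with the population size at each bin start.  Marker data:
per-cell noisy phenotype-marker measurements at sampling times.

Each container wraps a pandas DataFrame with a fixed schema plus a metadata
dictionary (generating parameters, seed, design) that serialises to a JSON
manifest next to the CSV.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import pandas as pd

from .model_core import TreatmentSchedule

__all__ = [
    "Condition",
    "CountDataset",
    "EventDataset",
    "MarkerDataset",
    "DEFAULT_SCHEDULES",
]

DEFAULT_SCHEDULES: Dict[str, TreatmentSchedule] = {
    "drug_on": TreatmentSchedule.continuous(True),
    "drug_off": TreatmentSchedule.continuous(False),
}

COUNT_COLUMNS = ["condition_id", "P", "schedule_id", "t_days", "replicate", "count"]
EVENT_COLUMNS = ["bin_start", "bin_end", "n_at_start", "n_prolif_events", "n_death_events"]
MARKER_COLUMNS = ["t_days", "cell_id", "marker_value"]


@dataclass(frozen=True)
class Condition:
    """One experimental condition: initial population type and schedule."""

    condition_id: str
    P: int
    schedule_id: str

    def schedule(self, schedules: Optional[Dict[str, TreatmentSchedule]] = None):
        return (schedules or DEFAULT_SCHEDULES)[self.schedule_id]


def _check_columns(df: pd.DataFrame, columns) -> pd.DataFrame:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"dataset missing columns: {missing}")
    return df[list(columns)].copy()


@dataclass
class CountDataset:
    """Terminal cell counts: one row per replicate well."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)
    schedules: Dict[str, TreatmentSchedule] = field(
        default_factory=lambda: dict(DEFAULT_SCHEDULES)
    )

    def __post_init__(self) -> None:
        self.df = _check_columns(self.df, COUNT_COLUMNS)
        if (self.df["count"] < 0).any():
            raise ValueError("counts must be nonnegative")

    def conditions(self):
        out = []
        for (cid, P, sid), _ in self.df.groupby(
            ["condition_id", "P", "schedule_id"], sort=True
        ):
            out.append(Condition(cid, int(P), sid))
        return out

    def to_csv(self, path) -> None:
        path = Path(path)
        self.df.to_csv(path, index=False)
        _write_manifest(path, self.metadata, self.schedules)

    @classmethod
    def from_csv(cls, path, schedules=None) -> "CountDataset":
        path = Path(path)
        meta, sched = _read_manifest(path)
        if schedules:
            sched.update(schedules)
        return cls(df=pd.read_csv(path), metadata=meta, schedules=sched)


@dataclass
class EventDataset:
    """Binned proliferation/death event counts from continuous observation."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = _check_columns(self.df, EVENT_COLUMNS)
        if (self.df[["n_prolif_events", "n_death_events", "n_at_start"]] < 0).any().any():
            raise ValueError("event and population counts must be nonnegative")
        starts = self.df["bin_start"].to_numpy()
        ends = self.df["bin_end"].to_numpy()
        if (ends <= starts).any():
            raise ValueError("bins must have positive width")

    def to_csv(self, path) -> None:
        path = Path(path)
        self.df.to_csv(path, index=False)
        _write_manifest(path, self.metadata, None)

    @classmethod
    def from_csv(cls, path) -> "EventDataset":
        path = Path(path)
        meta, _ = _read_manifest(path)
        return cls(df=pd.read_csv(path), metadata=meta)


@dataclass
class MarkerDataset:
    """Per-cell marker measurements at sampling times."""

    df: pd.DataFrame
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.df = _check_columns(self.df, MARKER_COLUMNS)

    def to_csv(self, path) -> None:
        path = Path(path)
        self.df.to_csv(path, index=False)
        _write_manifest(path, self.metadata, None)

    @classmethod
    def from_csv(cls, path) -> "MarkerDataset":
        path = Path(path)
        meta, _ = _read_manifest(path)
        return cls(df=pd.read_csv(path), metadata=meta)


def _manifest_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".manifest.json")


def _write_manifest(csv_path: Path, metadata: dict, schedules) -> None:
    doc = {"metadata": metadata}
    if schedules is not None:
        doc["schedules"] = {
            sid: {"initial_state": s.initial_state, "switch_times": list(s.switch_times)}
            for sid, s in schedules.items()
        }
    _manifest_path(csv_path).write_text(json.dumps(doc, indent=1, default=float))


def _read_manifest(csv_path: Path):
    mpath = _manifest_path(csv_path)
    meta: dict = {}
    sched = dict(DEFAULT_SCHEDULES)
    if mpath.exists():
        doc = json.loads(mpath.read_text())
        meta = doc.get("metadata", {})
        for sid, s in doc.get("schedules", {}).items():
            sched[sid] = TreatmentSchedule(
                initial_state=s["initial_state"], switch_times=tuple(s["switch_times"])
            )
    return meta, sched
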