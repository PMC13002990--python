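"""File formats: observation CSV, schedule YAML/JSON, parameter/subject JSON.

Dataset CSV columns: study_id, experiment_id, observable, time_min, value,
sem, n.  Parse errors are structured (they carry the offending row number)
and unknown observable names are rejected with the allowed list.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .inference import Dataset, Experiment, Observation
from .model import OBSERVABLE_NAMES
from .params import Anthropometrics, ParameterSet
from .schedule import InputSchedule

__all__ = [
    "DatasetFormatError", "RunConfig", "read_dataset", "write_dataset",
    "read_schedule", "write_schedule", "read_anthropometrics",
    "write_anthropometrics", "data_path", "config_hash",
]


@dataclass
class RunConfig:
    """Validated file paths and settings of one analysis run.

    The CLI commands assemble one of these implicitly from their options;
    it is exposed for programmatic use and for hashing into run logs.
    """

    schedule_path: Path | None = None
    subject_path: Path | None = None
    params_path: Path | None = None
    dataset_path: Path | None = None
    output_dir: Path | None = None
    alpha: float = 0.05
    seed: int | None = None
    stochastic: bool = False
    optimizer: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0 < self.alpha < 1:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        if self.stochastic and self.seed is None:
            raise ValueError("a seed is required for stochastic commands")
        for name in ("schedule_path", "subject_path", "params_path",
                     "dataset_path"):
            p = getattr(self, name)
            if p is not None:
                p = Path(p)
                setattr(self, name, p)
                if not p.exists():
                    raise FileNotFoundError(f"{name}: {p} does not exist")

    def hash(self) -> str:
        return config_hash({k: str(v) for k, v in self.__dict__.items()})

DATASET_COLUMNS = ("study_id", "experiment_id", "observable", "time_min",
                   "value", "sem", "n")


class DatasetFormatError(ValueError):
    def __init__(self, message: str, row: int | None = None):
        prefix = f"row {row}: " if row is not None else ""
        super().__init__(prefix + message)
        self.row = row


def read_dataset(path, experiments: dict[str, Experiment] | None = None) -> Dataset:
    """Read an observation table; optionally attach experiment definitions.

    Without ``experiments``, a permissive placeholder experiment (no drinks,
    horizon spanning the data) is attached per experiment_id so a file can
    be loaded and inspected before its schedules are known.
    """
    try:
        df = pd.read_csv(path)
    except Exception as err:  # pragma: no cover - delegated to pandas
        raise DatasetFormatError(f"cannot parse {path}: {err}") from err
    missing = set(DATASET_COLUMNS) - set(df.columns)
    if missing:
        raise DatasetFormatError(f"missing columns: {sorted(missing)}")
    observations = []
    for i, row in df.iterrows():
        rowno = int(i) + 2  # header is line 1
        obs_name = str(row["observable"])
        if obs_name not in OBSERVABLE_NAMES:
            raise DatasetFormatError(
                f"unknown observable {obs_name!r}; allowed: {OBSERVABLE_NAMES}",
                row=rowno)
        try:
            t, v, sem = float(row["time_min"]), float(row["value"]), float(row["sem"])
            n = int(row["n"])
        except (TypeError, ValueError) as err:
            raise DatasetFormatError(f"malformed number: {err}", row=rowno) from err
        if not sem > 0:
            raise DatasetFormatError(f"SEM must be positive, got {sem}", row=rowno)
        observations.append(Observation(
            study_id=str(row["study_id"]), experiment_id=str(row["experiment_id"]),
            observable=obs_name, time=t, value=v, sem=sem, n=n))
    if experiments is None:
        horizon = max((o.time for o in observations), default=0.0)
        experiments = {eid: Experiment(schedule=InputSchedule(horizon=horizon),
                                       anthro=Anthropometrics("male", 80.0, 1.8, 40.0))
                       for eid in {o.experiment_id for o in observations}}
    return Dataset(observations=observations, experiments=experiments)


def write_dataset(dataset: Dataset, path) -> None:
    dataset.df.to_csv(path, index=False)


def read_schedule(path) -> InputSchedule:
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    return InputSchedule.from_dict(payload)


def write_schedule(schedule: InputSchedule, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(schedule.to_dict(), fh, sort_keys=False)


def read_anthropometrics(path) -> Anthropometrics:
    with open(path) as fh:
        return Anthropometrics.from_dict(json.load(fh))


def write_anthropometrics(anthro: Anthropometrics, path) -> None:
    with open(path, "w") as fh:
        json.dump(anthro.to_dict(), fh, indent=1)


def data_path(name: str) -> Path:
    """Path of a fixture shipped with the package (parameters, subjects, protocols)."""
    return Path(__file__).parent / "data" / name


def config_hash(payload: dict) -> str:
    """Stable short hash of a run configuration, recorded in outputs."""
    blob = json.dumps(payload, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
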