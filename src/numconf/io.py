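"""Readers, writers and configuration for the pipeline.

All tables are CSV with a header; RTs are seconds everywhere.  Output
files embed the run seed and a configuration hash as leading ``#``
comment lines so every artifact is traceable to the run that produced
it; :func:`read_table` skips those lines transparently.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .design import NumeralType

__all__ = [
    "SchemaError",
    "RunConfig",
    "config_hash",
    "read_trials",
    "read_table",
    "write_table",
    "write_json",
]

TRIAL_COLUMNS = ("subject", "numeral_type", "num_a", "num_b", "log_distance", "rt", "correct")
_VALID_TYPES = {t.value for t in NumeralType}


class SchemaError(ValueError):
    """A table does not conform to the documented trial schema."""


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration."""

    experiment: str = "exp1"
    seed: int = 0
    n_subjects: int = 5
    trials_per_pair_per_type: int | None = None
    n_dummy: int | None = None
    un_mode: str = "equal"
    sims_per_distance: int = 150
    fit: bool = True
    fast_fit: bool = True
    out_dir: str = "numconf_run"

    @classmethod
    def from_json(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls(**json.load(fh))

    def to_dict(self) -> dict:
        return dict(self.__dict__)


def config_hash(config) -> str:
    """Stable short hash of a configuration mapping or RunConfig."""
    if isinstance(config, RunConfig):
        config = config.to_dict()
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def write_table(frame: pd.DataFrame, path, seed: int | None = None, config=None) -> None:
    """Write a CSV with provenance comment lines (seed, config hash)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        if config is not None:
            fh.write(f"# config_sha256: {config_hash(config)}\n")
        frame.to_csv(fh, index=False)


def read_table(path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")


def read_trials(path, deadline_s: float = 3.0) -> pd.DataFrame:
    """Read and validate a trial table.

    Checks mandatory columns, numeral-type values and RT unit sanity
    (an RT above the task deadline on every row suggests milliseconds
    were supplied; a warning is raised).  Malformed rows raise
    :class:`SchemaError` naming the offending rows.
    """
    frame = read_table(path)
    missing = [c for c in TRIAL_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(f"missing mandatory column(s): {', '.join(missing)}")
    bad = ~frame["numeral_type"].isin(_VALID_TYPES)
    if bad.any():
        rows = frame.index[bad].tolist()[:10]
        raise SchemaError(
            f"unknown numeral_type in row(s) {rows}: "
            f"{sorted(frame.loc[bad, 'numeral_type'].unique())}"
        )
    rt = pd.to_numeric(frame["rt"], errors="coerce")
    responded = rt.notna()
    if responded.any() and (rt[responded] > deadline_s).all():
        warnings.warn(
            "every RT exceeds the task deadline; values look like "
            "milliseconds — RTs must be seconds",
            UserWarning,
            stacklevel=2,
        )
    return frame


def write_json(obj: dict, path, seed: int | None = None, config=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = dict(obj)
    if seed is not None:
        payload["seed"] = seed
    if config is not None:
        payload["config_sha256"] = config_hash(config)
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=str)
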