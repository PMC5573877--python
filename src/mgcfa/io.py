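"""Input/output helpers: CSV and moment-matrix loading, JSON reports."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import GroupMoments, moments_from_matrices

__all__ = [
    "SCHEMA_VERSION",
    "RunConfig",
    "load_table",
    "load_moments",
    "write_report",
    "read_report",
]

SCHEMA_VERSION = 1


from dataclasses import dataclass, field


@dataclass
class RunConfig:
    """Resolved configuration of a CLI run.

    Mirrors the command-line flags; a YAML file with the same keys can be
    passed via ``--config`` to pre-populate them. The seed is recorded in
    every output artifact.
    """

    model: str | None = None
    data: str | None = None
    moments: list = field(default_factory=list)
    n: list = field(default_factory=list)
    group: str = "group"
    seed: int | None = None
    B: int = 500
    alpha: float = 0.05
    cfi_cutoff: float = 0.95
    rmsea_cutoff: float = 0.06
    out: str | None = None

    def validate(self) -> None:
        for label, p in [("model", self.model), ("data", self.data)] + [
            ("moments", m) for m in self.moments
        ]:
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{label} path does not exist: {p}")
        if self.moments and len(self.moments) != len(self.n):
            raise ValueError("one --n per --moments matrix is required")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)


def load_table(path: str | Path, group_column: str) -> pd.DataFrame:
    """Read a per-subject CSV: numeric indicator columns + one group column.

    Rows with missing values in any used column are rejected (callers must
    pre-filter), matching the listwise-complete contract of the estimator.
    """
    table = pd.read_csv(path)
    if group_column not in table.columns:
        raise ValueError(
            f"{path}: group column {group_column!r} not found "
            f"(columns: {list(table.columns)})"
        )
    return table


def load_moments(
    matrix_paths: list[str | Path], ns: list[int], names: list[str] | None = None
) -> GroupMoments:
    """Load per-group covariance matrices from whitespace-delimited text files."""
    covs = [np.loadtxt(p) for p in matrix_paths]
    return moments_from_matrices(covs, ns, names=names)


def _file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def _jsonable(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, np.bool_):
        return bool(obj)
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_report(
    results: dict,
    path: str | Path,
    seed=None,
    input_paths: list[str | Path] | None = None,
) -> Path:
    """Write a JSON report: schema version, seed, input hashes, statistics.

    Statistics are stored at full precision; a ``display`` block repeats the
    scalar statistics rounded to 2 decimals for side-by-side reading.
    """
    path = Path(path)
    payload = {
        "schema_version": SCHEMA_VERSION,
        "seed": None if seed is None else str(seed),
        "inputs": {
            str(p): _file_sha256(p) for p in (input_paths or [])
        },
        "results": _jsonable(results),
    }
    display = {}
    for key, val in payload["results"].items():
        if isinstance(val, float):
            display[key] = round(val, 2)
    payload["display"] = display
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    return path


def read_report(path: str | Path) -> dict:
    return json.loads(Path(path).read_text())
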