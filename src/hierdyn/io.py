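"""File formats and run configuration.

All tabular output is comma-separated UTF-8 with a mandatory header and
full-precision floats, so outputs diff cleanly and round-trip through the
module's own readers without loss.  Longitudinal hierarchy tables follow the
shape of deposited empirical datasets: one row per individual per period
with columns ``group, period, id, position`` (position 1 = top).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .dynamics import LongitudinalHierarchy
from .markov import StateSpace, SteadyState, TransitionMatrix

__all__ = [
    "ValidationError",
    "RunConfig",
    "RunManifest",
    "read_hierarchy_csv",
    "write_hierarchy_csv",
    "write_transition_matrix",
    "read_transition_matrix",
    "write_steady_state",
    "read_steady_state",
    "atomic_write_text",
]

FLOAT_FORMAT = "%.17g"


class ValidationError(ValueError):
    """Malformed input table; the message names the offending rows."""


def read_hierarchy_csv(path) -> list[LongitudinalHierarchy]:
    """Read longitudinal hierarchy tables, one object per group.

    Validates that within each group-period the positions are exactly
    1..n and ids are unique; violations raise :class:`ValidationError`
    naming the group, period, and problem.
    """
    df = pd.read_csv(path)
    required = ["group", "period", "id", "position"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValidationError(f"{path}: missing required columns {missing}")
    if df["position"].isna().any() or df["period"].isna().any():
        bad = df.index[df["position"].isna() | df["period"].isna()] + 2
        raise ValidationError(f"{path}: unparseable rows at lines {list(bad[:5])}")
    out = []
    for group, gdf in df.groupby("group", sort=True):
        periods: dict[int, list] = {}
        for period, pdf in gdf.groupby("period", sort=True):
            ids = pdf["id"].tolist()
            if len(set(ids)) != len(ids):
                dup = pdf["id"][pdf["id"].duplicated()].iloc[0]
                raise ValidationError(
                    f"group {group!r}, period {period}: duplicated id {dup!r}"
                )
            pos = sorted(pdf["position"].astype(int))
            if pos != list(range(1, len(pos) + 1)):
                raise ValidationError(
                    f"group {group!r}, period {period}: positions must be 1..n, got {pos}"
                )
            ordered = pdf.sort_values("position")["id"].tolist()
            periods[int(period)] = ordered
        out.append(LongitudinalHierarchy(group=str(group), periods=periods))
    return out


def write_hierarchy_csv(hierarchies, path) -> None:
    rows = []
    for h in hierarchies:
        for period in h.period_labels:
            for p, ind in enumerate(h.periods[period], start=1):
                rows.append({"group": h.group, "period": period, "id": ind, "position": p})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_transition_matrix(tm: TransitionMatrix, prefix) -> tuple[Path, Path]:
    """Write probability and count matrices as labelled CSVs."""
    prefix = Path(prefix)
    labels = tm.state_space.labels
    p_path = prefix.parent / (prefix.name + ".probs.csv")
    c_path = prefix.parent / (prefix.name + ".counts.csv")
    pd.DataFrame(tm.probabilities, index=labels, columns=labels).to_csv(
        p_path, float_format=FLOAT_FORMAT, index_label="state"
    )
    pd.DataFrame(tm.counts, index=labels, columns=labels).to_csv(
        c_path, index_label="state"
    )
    return p_path, c_path


def read_transition_matrix(probs_path, counts_path=None) -> TransitionMatrix:
    pdf = pd.read_csv(probs_path, index_col="state", float_precision="round_trip")
    queen_mode = "Q" in pdf.index
    P = pdf.to_numpy(dtype=float)
    if counts_path is not None:
        counts = pd.read_csv(counts_path, index_col="state").to_numpy(dtype=np.int64)
    else:
        counts = np.zeros_like(P, dtype=np.int64)
    return TransitionMatrix(
        counts=counts, probabilities=P, state_space=StateSpace(queen_mode=queen_mode)
    )


def write_steady_state(ss: SteadyState, space: StateSpace, path) -> None:
    payload = {
        "states": space.labels,
        "pi": [float(x) for x in ss.pi],
        "rows": [[float(x) for x in row] for row in ss.rows],
        "ergodic": ss.ergodic,
        "iterations": ss.iterations,
        "epsilon": ss.epsilon,
    }
    atomic_write_text(path, json.dumps(payload, indent=1))


def read_steady_state(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


@dataclass
class RunConfig:
    """Full configuration of a four-condition reproduction run.

    Serializes to YAML and back identically, so a run is restartable from
    its own config snapshot.
    """

    seed: int = 1
    out_dir: str = "hierdyn_out"
    # society parameters
    n: int = 30
    n_updates: int = 1200
    burn_in: int = 200
    n_replicates: int = 100
    reproduction_slope: float | None = None
    # markov / inequality parameters
    epsilon: float = 0.001
    trajectory_length: int = 120
    n_trajectories: int = 10_000

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "RunConfig":
        data = yaml.safe_load(text) or {}
        unknown = set(data) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValidationError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class RunManifest:
    """Provenance record of a completed run: config, seeds, output digests."""

    config: dict[str, Any]
    package_version: str
    stage_seeds: dict[str, int] = field(default_factory=dict)
    checksums: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def write(self, path) -> None:
        atomic_write_text(path, json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True))


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def atomic_write_text(path, text: str) -> None:
    path = Path(path)
    tmp = path.with_suffix(path.suffix + ".tmp")
    tmp.write_text(text)
    os.replace(tmp, path)
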