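"""File formats and run manifests.

The interchange format for release data is a plain CSV (UTF-8, comma
separators, period decimals, header required) with columns::

    sample_id, condition, size, time_h, release_ug_cm2

``condition`` and ``size`` are optional free-text context columns.  Times
are delivery-relative hours.  Reading validates hard (missing columns,
non-numeric cells, duplicated or out-of-order times are rejected with row
numbers) because silent CSV coercion is the classic way release datasets rot.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model_core import ReleaseProfile
from .radial_solver import SimulationResult

__all__ = [
    "read_release_csv",
    "write_release_csv",
    "simulation_frames",
    "RunManifest",
]

logger = logging.getLogger(__name__)

_REQUIRED_COLUMNS = ("sample_id", "time_h", "release_ug_cm2")
_OPTIONAL_COLUMNS = ("condition", "size")


def write_release_csv(profiles: list[ReleaseProfile], path: str | Path) -> None:
    """Write profiles in the standard release CSV layout (deterministic:
    identical profiles produce byte-identical files)."""
    rows = []
    for prof in profiles:
        frame = pd.DataFrame(
            {
                "sample_id": prof.sample_id,
                "condition": prof.metadata.get("condition", ""),
                "size": prof.metadata.get("size", ""),
                "time_h": prof.times,
                "release_ug_cm2": prof.release_per_area,
            }
        )
        rows.append(frame)
    out = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["sample_id", *_OPTIONAL_COLUMNS, "time_h", "release_ug_cm2"])
    )
    out.to_csv(path, index=False, lineterminator="\n")


def read_release_csv(path: str | Path) -> list[ReleaseProfile]:
    """Read and validate a standard release CSV into profiles grouped by
    ``sample_id`` (order of first appearance preserved).

    Raises ``ValueError`` naming the offending data row (1-based, excluding
    the header) for missing columns, non-numeric cells, duplicate
    (sample, time) pairs, or out-of-order times within a sample.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in _REQUIRED_COLUMNS if c not in raw.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}; header must contain {_REQUIRED_COLUMNS}")
    if len(raw) == 0:
        logger.warning("%s: empty data section, returning no profiles", path)
        return []

    numeric = {}
    for col in ("time_h", "release_ug_cm2"):
        converted = pd.to_numeric(raw[col], errors="coerce")
        bad = converted.isna() & (raw[col].astype(str).str.strip() != "")
        bad |= raw[col].astype(str).str.strip() == ""
        if bad.any():
            rows = [int(i) + 1 for i in raw.index[bad][:5]]
            raise ValueError(f"{path}: non-numeric {col!r} values at data rows {rows}")
        numeric[col] = converted.to_numpy(dtype=float)

    dup = raw.duplicated(subset=["sample_id", "time_h"], keep=False)
    if dup.any():
        rows = [int(i) + 1 for i in raw.index[dup][:5]]
        raise ValueError(f"{path}: duplicate (sample_id, time_h) pairs at data rows {rows}")

    profiles: list[ReleaseProfile] = []
    for sample_id in raw["sample_id"].drop_duplicates():
        mask = (raw["sample_id"] == sample_id).to_numpy()
        idx = np.flatnonzero(mask)
        t = numeric["time_h"][mask]
        q = numeric["release_ug_cm2"][mask]
        order_bad = np.flatnonzero(np.diff(t) <= 0)
        if len(order_bad):
            row = int(idx[order_bad[0] + 1]) + 1
            raise ValueError(
                f"{path}: times for sample {sample_id!r} not strictly increasing "
                f"(first out-of-order data row: {row})"
            )
        meta = {}
        for col in _OPTIONAL_COLUMNS:
            if col in raw.columns:
                val = str(raw[col].iloc[idx[0]])
                if val:
                    meta[col] = val
        profiles.append(
            ReleaseProfile(sample_id=str(sample_id), times=t, release_per_area=q, metadata=meta)
        )
    return profiles


def simulation_frames(result: SimulationResult) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Tidy exports of a simulation: a wall table (stage, time_h, r_cm,
    concentration_ug_cm3) and a reservoir table (stage, time_h, CD_ug_cm3,
    release_ug_cm2)."""
    n = result.grid.n_nodes
    wall = pd.DataFrame(
        {
            "stage": np.repeat(result.wall_stages, n),
            "time_h": np.repeat(result.wall_times, n),
            "r_cm": np.tile(result.grid.nodes, len(result.wall_times)),
            "concentration_ug_cm3": result.wall_states.ravel(),
        }
    )
    area = result.geometry.external_area()
    if result.params.sink_delivery:
        release = (result.delivery_wall_mass[0] - result.delivery_wall_mass) / area
    else:
        release = result.reservoir_concentration * result.params.reservoir_volume / area
    reservoir = pd.DataFrame(
        {
            "stage": "delivery",
            "time_h": result.delivery_times,
            "CD_ug_cm3": result.reservoir_concentration,
            "release_ug_cm2": release,
        }
    )
    return wall, reservoir


@dataclass
class RunManifest:
    """Record of one CLI run, sufficient to re-run the command exactly:
    the subcommand, the fully resolved configuration (defaults
    materialised), the seed, the artifacts written, and the wall-clock
    duration."""

    subcommand: str
    config: dict
    seed: int | None
    artifacts: list[str] = field(default_factory=list)
    duration_s: float = 0.0

    def write(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2, sort_keys=True) + "\n")

    @classmethod
    def read(cls, path: str | Path) -> "RunManifest":
        data = json.loads(Path(path).read_text())
        return cls(**data)
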