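"""Reading and writing trajectories and analysis records.

The on-disk trajectory format is one CSV per subject per session with a
header row and columns ``t,x,y`` (missing samples as empty fields), plus a
sidecar YAML or JSON metadata file carrying subject_id, size_class,
condition, frame_rate and arena_bounds.  Other column layouts — including
those of externally deposited datasets — are accepted through a column map
``{"t": <name>, "x": <name>, "y": <name>}``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
import yaml

from .kinematics import Trajectory

__all__ = ["read_trajectory", "write_trajectory", "sidecar_path"]

DEFAULT_COLUMNS = {"t": "t", "x": "x", "y": "y"}


def sidecar_path(csv_path: str | Path) -> Path:
    """Preferred metadata path for a trajectory CSV (<stem>.meta.yaml)."""
    p = Path(csv_path)
    return p.with_suffix("").with_suffix(".meta.yaml")


def _load_metadata(path: Path) -> dict:
    text = path.read_text()
    if path.suffix == ".json":
        return json.loads(text)
    return yaml.safe_load(text)


def read_trajectory(
    csv_path: str | Path,
    metadata: str | Path | dict | None = None,
    column_map: dict[str, str] | None = None,
) -> Trajectory:
    """Read a trajectory CSV plus its metadata sidecar.

    ``metadata`` may be a dict, an explicit YAML/JSON path, or None to look
    for ``<stem>.meta.yaml`` (then ``.meta.json``) next to the CSV.
    ``column_map`` renames non-standard columns, e.g.
    ``{"t": "time_s", "x": "pos_x", "y": "pos_y"}``.
    """
    csv_path = Path(csv_path)
    cols = dict(DEFAULT_COLUMNS)
    if column_map:
        cols.update(column_map)
    df = pd.read_csv(csv_path)
    missing = [c for c in cols.values() if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns {missing} in {csv_path.name}")

    if metadata is None:
        for cand in (sidecar_path(csv_path), csv_path.with_suffix("").with_suffix(".meta.json")):
            if cand.exists():
                metadata = cand
                break
        else:
            raise FileNotFoundError(f"no metadata sidecar found for {csv_path.name}")
    if not isinstance(metadata, dict):
        metadata = _load_metadata(Path(metadata))

    return Trajectory(
        t=df[cols["t"]].to_numpy(dtype=float),
        x=df[cols["x"]].to_numpy(dtype=float),
        y=df[cols["y"]].to_numpy(dtype=float),
        frame_rate=float(metadata["frame_rate"]),
        arena_bounds=tuple(metadata["arena_bounds"]),
        subject_id=str(metadata.get("subject_id", csv_path.stem)),
        size_class=metadata.get("size_class", "small"),
        condition=metadata.get("condition", "control"),
    )


def write_trajectory(traj: Trajectory, csv_path: str | Path) -> Path:
    """Write a trajectory CSV and its YAML metadata sidecar.

    Missing samples (NaN positions) become empty fields.  Returns the
    sidecar path.
    """
    csv_path = Path(csv_path)
    csv_path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame({"t": traj.t, "x": traj.x, "y": traj.y})
    df.to_csv(csv_path, index=False, float_format="%.6f", na_rep="")
    meta = {
        "subject_id": traj.subject_id,
        "size_class": traj.size_class.value,
        "condition": traj.condition.value,
        "frame_rate": float(traj.frame_rate),
        "arena_bounds": [float(v) for v in traj.arena_bounds],
    }
    side = sidecar_path(csv_path)
    side.write_text(yaml.safe_dump(meta, sort_keys=False))
    return side
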