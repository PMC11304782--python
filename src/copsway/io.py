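"""Reading and writing COP trajectory files and experiment configuration.

On-disk dialect (modeled on stabilometry-software CSV exports)::

    # participant_id=P03
    # condition=ears_free
    # trial=1
    time_s,cop_x_mm,cop_y_mm
    0.00,0.1,-0.2
    ...

Metadata lines are ``# key=value`` and must precede the header; the header
must read exactly ``time_s,cop_x_mm,cop_y_mm``.  Units are fixed to seconds
and millimetres — files in other units are rejected rather than converted.
Coordinate convention: x positive = participant's left, y positive = anterior.
"""

from __future__ import annotations

import io as _io
from os import PathLike
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import yaml

from .exceptions import FormatError, ValidationError
from .trajectory import CopTrajectory, ExperimentConfig, StimulusSchedule

HEADER = "time_s,cop_x_mm,cop_y_mm"

_PathType = Union[str, PathLike]


def read_cop_csv(path: _PathType) -> CopTrajectory:
    """Read one COP trajectory file.

    Raises
    ------
    FormatError
        Malformed header, metadata, or non-numeric body.
    ValidationError
        Values violating a trajectory invariant (non-monotone time,
        unknown condition, too few samples).
    """
    path = Path(path)
    meta: dict[str, str] = {}
    with open(path, "r", encoding="utf-8") as fh:
        lines = fh.readlines()
    i = 0
    for i, line in enumerate(lines):
        stripped = line.strip()
        if stripped.startswith("#"):
            body = stripped[1:].strip()
            if "=" not in body:
                raise FormatError(f"{path}: metadata line without '=': {stripped!r}")
            key, _, value = body.partition("=")
            meta[key.strip()] = value.strip()
        else:
            break
    else:
        raise FormatError(f"{path}: no header line found")
    if lines[i].strip() != HEADER:
        raise FormatError(
            f"{path}: expected header {HEADER!r}, got {lines[i].strip()!r}"
        )
    body_text = "".join(lines[i + 1 :])
    try:
        frame = pd.read_csv(
            _io.StringIO(body_text), header=None, names=["t", "x", "y"], dtype=float
        )
    except ValueError as exc:
        raise FormatError(f"{path}: non-numeric data row ({exc})") from exc
    if frame.shape[1] != 3:
        raise FormatError(f"{path}: expected 3 columns")
    if "condition" not in meta:
        raise ValidationError(f"{path}: required metadata key 'condition' missing")
    trial_raw = meta.get("trial", "1")
    try:
        trial = int(trial_raw)
    except ValueError as exc:
        raise FormatError(f"{path}: trial metadata not an integer: {trial_raw!r}") from exc
    return CopTrajectory(
        t=frame["t"].to_numpy(),
        x=frame["x"].to_numpy(),
        y=frame["y"].to_numpy(),
        participant_id=meta.get("participant_id", "unknown"),
        condition=meta["condition"],
        trial_index=trial,
    )


def write_cop_csv(traj: CopTrajectory, path: _PathType) -> Path:
    """Write a trajectory in the dialect read by :func:`read_cop_csv`.

    Numeric fields are written with 12 significant digits so a round trip
    reproduces coordinates to well below 1e-9 mm.
    """
    path = Path(path)
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"# participant_id={traj.participant_id}\n")
        fh.write(f"# condition={traj.condition}\n")
        fh.write(f"# trial={traj.trial_index}\n")
        fh.write(HEADER + "\n")
        for t, x, y in zip(traj.t, traj.x, traj.y):
            fh.write(f"{t:.12g},{x:.12g},{y:.12g}\n")
    return path


def load_experiment_config(path: _PathType) -> ExperimentConfig:
    """Load an experiment configuration from a YAML file.

    An empty file (or empty mapping) yields the default protocol: five
    conditions, two trials per headphone condition, 60-s records, 10
    alternating pannings of 1,000 ms with 5-s pauses.
    """
    path = Path(path)
    with open(path, "r", encoding="utf-8") as fh:
        raw = yaml.safe_load(fh)
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise FormatError(f"{path}: top level must be a mapping")
    return experiment_config_from_dict(raw, source=str(path))


def experiment_config_from_dict(raw: dict, source: str = "<config>") -> ExperimentConfig:
    known = {
        "conditions",
        "trials_per_condition",
        "record_duration_s",
        "sampling_rate_hz",
        "schedule",
        "sound_levels",
    }
    unknown = set(raw) - known
    if unknown:
        raise FormatError(f"{source}: unknown config keys {sorted(unknown)}")
    kwargs: dict = {}
    for key in known - {"schedule", "sound_levels", "conditions"}:
        if key in raw:
            kwargs[key] = raw[key]
    if "conditions" in raw:
        kwargs["conditions"] = tuple(raw["conditions"])
    if "schedule" in raw:
        sched = raw["schedule"]
        if not isinstance(sched, dict):
            raise FormatError(f"{source}: schedule must be a mapping")
        kwargs["schedule"] = StimulusSchedule(**sched)
    if "sound_levels" in raw:
        levels = raw["sound_levels"]
        if not isinstance(levels, dict):
            raise FormatError(f"{source}: sound_levels must be a mapping")
        kwargs["sound_levels"] = {
            cond: dict(vals) for cond, vals in levels.items()
        }
    try:
        return ExperimentConfig(**kwargs)
    except TypeError as exc:
        raise FormatError(f"{source}: {exc}") from exc


def read_manifest(path: _PathType) -> list[CopTrajectory]:
    """Read a cohort manifest CSV (columns: participant_id, condition, trial,
    path) and load every referenced trajectory.

    Relative paths are resolved against the manifest's directory.  The
    metadata inside each trajectory file must agree with the manifest row.
    """
    path = Path(path)
    frame = pd.read_csv(path)
    required = {"participant_id", "condition", "trial", "path"}
    if not required.issubset(frame.columns):
        raise FormatError(
            f"{path}: manifest needs columns {sorted(required)}, "
            f"got {list(frame.columns)}"
        )
    out = []
    for row in frame.itertuples(index=False):
        fpath = Path(row.path)
        if not fpath.is_absolute():
            fpath = path.parent / fpath
        traj = read_cop_csv(fpath)
        if (
            traj.participant_id != str(row.participant_id)
            or traj.condition != row.condition
            or traj.trial_index != int(row.trial)
        ):
            raise ValidationError(
                f"{fpath}: file metadata disagrees with manifest row "
                f"({row.participant_id}, {row.condition}, trial {row.trial})"
            )
        out.append(traj)
    return out


def write_manifest(trajectories, paths, out_path: _PathType) -> Path:
    """Write a manifest CSV for trajectories stored at the given paths."""
    out_path = Path(out_path)
    rows = [
        {
            "participant_id": tr.participant_id,
            "condition": tr.condition,
            "trial": tr.trial_index,
            "path": str(p),
        }
        for tr, p in zip(trajectories, paths)
    ]
    pd.DataFrame(rows).to_csv(out_path, index=False)
    return out_path
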