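"""On-disk data model: pose tables, cohort manifests and result files.

Pose tables are long-format CSV (assay_id, frame, point_id, x, y,
likelihood) with '#'-prefixed header metadata lines (frame_rate,
flow_schedule, arena, coordinate convention, units).  Episode intervals use
0-based, half-open [start, end) frame spans.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import N_KEYPOINTS, PoseSequence

_CONVENTION = ("x right, y toward flow source, origin bottom-left; "
               "point_id 0-9 centerline head->tail-base, 10 tail tip; px")
POSE_COLUMNS = ["assay_id", "frame", "point_id", "x", "y", "likelihood"]


def write_pose_table(seq: PoseSequence, path: str | Path,
                     assay_id: str = "assay") -> Path:
    """Write one assay's pose sequence as a long-format CSV."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    n = seq.n_frames
    frames = np.repeat(np.arange(n), N_KEYPOINTS)
    points = np.tile(np.arange(N_KEYPOINTS), n)
    df = pd.DataFrame({
        "assay_id": assay_id, "frame": frames, "point_id": points,
        "x": seq.xy.reshape(-1, 2)[:, 0], "y": seq.xy.reshape(-1, 2)[:, 1],
        "likelihood": seq.likelihood.reshape(-1)})
    header = {
        "frame_rate": seq.frame_rate,
        "flow_schedule": [[float(v), float(d)] for v, d in seq.flow_schedule],
        "arena": [float(v) for v in seq.arena],
        "convention": _CONVENTION,
        "meta": {k: str(v) for k, v in seq.meta.items()},
    }
    with open(path, "w") as fh:
        for k, v in header.items():
            fh.write(f"# {k}: {json.dumps(v)}\n")
        df.to_csv(fh, index=False)
    return path


def read_pose_table(path: str | Path) -> PoseSequence:
    """Read a pose table written by :func:`write_pose_table`.

    Raises a descriptive error on schema violations (missing columns,
    non-monotone frames, out-of-range point ids).
    """
    path = Path(path)
    header: dict = {}
    with open(path) as fh:
        pos = fh.tell()
        line = fh.readline()
        while line.startswith("#"):
            key, _, val = line[1:].strip().partition(":")
            header[key.strip()] = json.loads(val.strip())
            pos = fh.tell()
            line = fh.readline()
        fh.seek(pos)
        df = pd.read_csv(fh)
    missing = [c for c in POSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path.name}: missing column(s) {missing}")
    if (df["point_id"] < 0).any() or (df["point_id"] >= N_KEYPOINTS).any():
        bad = df.index[(df["point_id"] < 0) | (df["point_id"] >= N_KEYPOINTS)][0]
        raise ValueError(f"{path.name}: point_id out of range at row {bad}")
    frames = df["frame"].unique()
    if not np.array_equal(frames, np.arange(len(frames))):
        raise ValueError(f"{path.name}: frames must be contiguous from 0")
    wide = df.sort_values(["frame", "point_id"])
    n = len(frames)
    xy = wide[["x", "y"]].to_numpy(dtype=float).reshape(n, N_KEYPOINTS, 2)
    lik = wide["likelihood"].to_numpy(dtype=float).reshape(n, N_KEYPOINTS)
    return PoseSequence(
        xy=xy, likelihood=lik,
        frame_rate=float(header.get("frame_rate", 70.0)),
        flow_schedule=tuple((v, d) for v, d in header.get(
            "flow_schedule", [[0.0, n / 70.0]])),
        arena=tuple(header.get("arena", (0.0, 0.0, 600.0, 1400.0))),
        meta=header.get("meta", {}))


def write_manifest(path: str | Path, fish: list[dict], outcome_file: str,
                   config: dict) -> Path:
    """Write the cohort manifest (fish records, file paths, config hash)."""
    path = Path(path)
    payload = {"fish": fish, "outcome_file": outcome_file,
               "config": config, "config_hash": config_hash(config)}
    path.write_text(yaml.safe_dump(payload, sort_keys=False))
    return path


def read_manifest(path: str | Path, check_files: bool = True) -> dict:
    path = Path(path)
    manifest = yaml.safe_load(path.read_text())
    if check_files:
        root = path.parent
        for rec in manifest["fish"]:
            for f in rec.get("assays", {}).values():
                if not (root / f).exists():
                    raise FileNotFoundError(f"manifest references missing file {f}")
        if not (root / manifest["outcome_file"]).exists():
            raise FileNotFoundError(
                f"manifest references missing file {manifest['outcome_file']}")
    return manifest


def config_hash(config: dict) -> str:
    return hashlib.sha1(
        json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_stamped_csv(df: pd.DataFrame, path: str | Path, config: dict,
                      seed: int | None = None) -> Path:
    """CSV with a comment header carrying the config hash and seed."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write(f"# config_hash: {config_hash(config)}\n")
        if seed is not None:
            fh.write(f"# seed: {seed}\n")
        df.to_csv(fh, index=False)
    return path


def read_stamped_csv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, comment="#")
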