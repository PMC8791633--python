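"""Readers and writers for the plain-text session layout.

One session is a directory holding a ``session.yaml`` manifest plus
delimited-text event tables:

* ``spikes.csv`` — column ``time_s``
* ``tracking.csv`` — ``time_s, led1_x_cm, led1_y_cm, led2_x_cm, led2_y_cm``
  (empty fields mark missing LED samples)
* ``pulses.csv`` — ``onset_s, duration_ms, power_mW, train_hz``

The manifest carries the session id, the recording span, relative paths of
the tables that exist, the arena geometry and free-form annotations.  Floats
are written with fixed precision (1 ns / 10 nm) so that write -> read is an
identity to well below analysis resolution and repeated writes of the same
session are byte-identical.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional

import numpy as np
import pandas as pd
import yaml

from .core import (LightPulseTrain, SessionRecord, SpikeTrain, TrackingTrace,
                   ValidationError)
from .geometry import MazeGeometry

_TIME_FMT = "%.9f"
_CM_FMT = "%.6f"


class ParseError(ValueError):
    """A session table or manifest could not be parsed."""


def _read_table(path: Path, columns: Iterable[str]) -> pd.DataFrame:
    if not path.exists():
        raise ParseError(f"{path}: file does not exist")
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed CSV
        raise ParseError(f"{path}: {exc}") from exc
    missing = set(columns) - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    for col in columns:
        bad = df.index[pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()]
        if len(bad):
            raise ParseError(f"{path}: non-numeric value in column {col!r} at row {int(bad[0])}")
    return df


def read_session(manifest_path: str | Path) -> SessionRecord:
    """Read and validate one session from its manifest."""
    manifest_path = Path(manifest_path)
    try:
        with open(manifest_path) as fh:
            manifest = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ParseError(f"{manifest_path}: {exc}") from exc
    if not isinstance(manifest, dict):
        raise ParseError(f"{manifest_path}: manifest must be a mapping")
    for key in ("session_id", "recording_span", "files"):
        if key not in manifest:
            raise ParseError(f"{manifest_path}: manifest missing key {key!r}")
    base = manifest_path.parent
    files = manifest["files"] or {}

    spikes_df = _read_table(base / files["spikes"], ["time_s"])
    spikes = SpikeTrain(
        times=spikes_df["time_s"].to_numpy(dtype=float),
        recording_span=tuple(manifest["recording_span"]),
    )

    tracking = None
    if files.get("tracking"):
        cols = ["time_s", "led1_x_cm", "led1_y_cm", "led2_x_cm", "led2_y_cm"]
        tdf = _read_table(base / files["tracking"], cols)
        tracking = TrackingTrace(
            t=tdf["time_s"].to_numpy(dtype=float),
            led1_xy=tdf[["led1_x_cm", "led1_y_cm"]].to_numpy(dtype=float),
            led2_xy=tdf[["led2_x_cm", "led2_y_cm"]].to_numpy(dtype=float),
        )

    pulses = None
    if files.get("pulses"):
        cols = ["onset_s", "duration_ms", "power_mW", "train_hz"]
        pdf = _read_table(base / files["pulses"], cols)
        pulses = LightPulseTrain(
            onsets=pdf["onset_s"].to_numpy(dtype=float),
            duration_ms=pdf["duration_ms"].to_numpy(dtype=float),
            power_mW=pdf["power_mW"].to_numpy(dtype=float),
            train_frequency_Hz=pdf["train_hz"].to_numpy(dtype=float),
        )

    arena = None
    if manifest.get("arena"):
        arena = MazeGeometry.from_dict(manifest["arena"])

    return SessionRecord(
        session_id=str(manifest["session_id"]),
        spikes=spikes,
        tracking=tracking,
        pulses=pulses,
        arena=arena,
        annotations=dict(manifest.get("annotations") or {}),
    )


def write_session(session: SessionRecord, directory: str | Path) -> Path:
    """Write one session into ``directory`` and return the manifest path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)

    files: dict = {"spikes": "spikes.csv"}
    pd.DataFrame({"time_s": session.spikes.times}).to_csv(
        directory / "spikes.csv", index=False, float_format=_TIME_FMT)

    if session.tracking is not None:
        tr = session.tracking
        df = pd.DataFrame({
            "time_s": tr.t,
            "led1_x_cm": tr.led1_xy[:, 0], "led1_y_cm": tr.led1_xy[:, 1],
            "led2_x_cm": tr.led2_xy[:, 0], "led2_y_cm": tr.led2_xy[:, 1],
        })
        # fixed formats per column: ns for time, 10 nm for positions
        df["time_s"] = df["time_s"].map(lambda v: _TIME_FMT % v)
        for col in df.columns[1:]:
            df[col] = df[col].map(lambda v: "" if np.isnan(v) else _CM_FMT % v)
        df.to_csv(directory / "tracking.csv", index=False)
        files["tracking"] = "tracking.csv"

    if session.pulses is not None:
        pu = session.pulses
        pd.DataFrame({
            "onset_s": pu.onsets,
            "duration_ms": pu.duration_ms,
            "power_mW": pu.power_mW,
            "train_hz": pu.train_frequency_Hz,
        }).to_csv(directory / "pulses.csv", index=False, float_format=_TIME_FMT)
        files["pulses"] = "pulses.csv"

    manifest = {
        "session_id": session.session_id,
        "recording_span": [float(session.spikes.recording_span[0]),
                           float(session.spikes.recording_span[1])],
        "files": files,
        "arena": session.arena.to_dict() if session.arena is not None else None,
        "annotations": dict(session.annotations),
    }
    manifest_path = directory / "session.yaml"
    with open(manifest_path, "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
    return manifest_path


def write_cohort(sessions, labels: Optional[pd.DataFrame], directory: str | Path) -> Path:
    """Write a list of sessions (one subdirectory each) plus an optional
    ``ground_truth.csv``; returns the cohort directory."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    seen = set()
    for session in sessions:
        if session.session_id in seen:
            raise ValidationError(f"duplicate session_id {session.session_id!r} in cohort")
        seen.add(session.session_id)
        write_session(session, directory / session.session_id)
    if labels is not None:
        labels.to_csv(directory / "ground_truth.csv", index=False)
    return directory


def read_cohort(directory: str | Path):
    """Read every session under ``directory`` (sorted by id); returns
    (sessions, ground_truth DataFrame or None)."""
    directory = Path(directory)
    manifests = sorted(directory.glob("*/session.yaml"))
    if not manifests:
        raise ParseError(f"{directory}: no session manifests found")
    sessions = [read_session(m) for m in manifests]
    gt_path = directory / "ground_truth.csv"
    labels = pd.read_csv(gt_path) if gt_path.exists() else None
    return sessions, labels
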