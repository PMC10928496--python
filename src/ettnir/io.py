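"""Session-log formats: CSV voltage logs with JSON sidecar manifests.

A session log is a CSV with fixed leading columns
``time_s, vp1_v, vp2_v, vp3_v, vp4_v, vp5_v`` and optional trailing columns
``ref_mm`` (reference-sensor displacement), ``rot_deg`` and ``cycle``.  A
sidecar ``<name>.manifest.json`` carries the schema tag, sampling rate,
seed, protocol and the board orientation.  Units are fixed in the headers
(seconds, volts, millimetres) to avoid unit ambiguity.

``board_orientation = "reversed"`` marks logs recorded with the detector
board rotated 180 degrees about its perpendicular axis (the bench-top
convention that avoids cable twist), in which the P1 and P3 channels trade
places; such logs have VP1 and VP3 swapped on load so downstream code always
sees the canonical orientation.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .electronics import VOLTAGE_COLUMNS, VoltageSeries

__all__ = ["write_session_log", "read_session_log"]

SCHEMA = "ettnir-session-1"
_OPTIONAL_COLUMNS = ("ref_mm", "rot_deg", "cycle")


def _manifest_path(csv_path: Path) -> Path:
    return csv_path.with_suffix(".manifest.json")


def write_session_log(
    series: VoltageSeries,
    path: str | Path,
    board_orientation: str = "standard",
) -> Path:
    """Write the CSV log and its JSON manifest; returns the CSV path."""
    path = Path(path)
    if board_orientation not in ("standard", "reversed"):
        raise ValueError("board_orientation must be 'standard' or 'reversed'")
    cols = ["time_s", *VOLTAGE_COLUMNS] + [
        c for c in _OPTIONAL_COLUMNS if c in series.frame.columns
    ]
    frame = series.frame.loc[:, cols]
    if board_orientation == "reversed":
        frame = frame.rename(columns={"vp1_v": "vp3_v", "vp3_v": "vp1_v"})[cols]
    frame.to_csv(path, index=False)  # str(float) round-trips binary64 exactly
    manifest = {
        "schema": SCHEMA,
        "sampling_rate_hz": series.sampling_rate_hz,
        "board_orientation": board_orientation,
        **series.metadata,
    }
    _manifest_path(path).write_text(json.dumps(manifest, indent=2))
    return path


def read_session_log(path: str | Path) -> VoltageSeries:
    """Read a session log, validating the schema and fixing the orientation."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    mpath = _manifest_path(path)
    if not mpath.exists():
        raise FileNotFoundError(f"missing manifest sidecar {mpath}")
    manifest = json.loads(mpath.read_text())
    if manifest.get("schema") != SCHEMA:
        raise ValueError(f"unrecognized session schema {manifest.get('schema')!r}")
    frame = pd.read_csv(path)
    required = ["time_s", *VOLTAGE_COLUMNS]
    missing = [c for c in required if c not in frame.columns]
    if missing:
        raise ValueError(f"session log {path} is missing columns {missing}")
    v = frame.loc[:, list(VOLTAGE_COLUMNS)].to_numpy()
    if np.any(~np.isfinite(v)):
        raise ValueError("session log contains non-finite voltages")
    if manifest.get("board_orientation") == "reversed":
        cols = list(frame.columns)
        frame = frame.rename(columns={"vp1_v": "vp3_v", "vp3_v": "vp1_v"})[cols]
    sampling_rate = float(manifest["sampling_rate_hz"])
    metadata = {k: v for k, v in manifest.items() if k not in ("schema", "sampling_rate_hz")}
    return VoltageSeries(frame, sampling_rate, metadata)
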