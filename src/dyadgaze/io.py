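"""On-disk formats: recordings, ground truth, trial metadata, results.

The canonical recording format is a single long-form CSV (gzip accepted
transparently via the ``.gz`` suffix) holding both agents' gaze (60 Hz)
and hand (120 Hz) streams.  Units: metres, seconds; milliseconds appear
only in reported SRTs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "RECORDING_COLUMNS",
    "SchemaError",
    "read_recording",
    "write_recording",
    "write_truth",
    "read_truth",
]

RECORDING_COLUMNS = [
    "time_s", "pair_id", "actor_id", "stream",
    "origin_x", "origin_y", "origin_z",
    "dir_x", "dir_y", "dir_z",
    "pos_x", "pos_y", "pos_z",
    "nasion_x", "nasion_y", "nasion_z",
    "validity", "trial_id",
]

_FLOAT_FMT = "%.9g"


class SchemaError(ValueError):
    """Recording file does not match the canonical schema."""


def write_recording(recording: pd.DataFrame, path) -> None:
    missing = [c for c in RECORDING_COLUMNS if c not in recording.columns]
    if missing:
        raise SchemaError(f"recording is missing columns: {missing}")
    recording[RECORDING_COLUMNS].to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_recording(path) -> pd.DataFrame:
    """Read and validate a recording CSV.

    Raises :class:`SchemaError` on missing/extra/reordered columns and
    ``ValueError`` (naming the first offending row) when timestamps are
    not non-decreasing within an (actor, stream) series.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    if list(df.columns) != RECORDING_COLUMNS:
        missing = [c for c in RECORDING_COLUMNS if c not in df.columns]
        extra = [c for c in df.columns if c not in RECORDING_COLUMNS]
        raise SchemaError(
            f"recording schema mismatch: missing={missing}, extra={extra}, "
            f"expected exact order {RECORDING_COLUMNS}")
    bad_stream = set(df["stream"].unique()) - {"gaze", "hand"}
    if bad_stream:
        raise SchemaError(f"unknown stream values: {sorted(bad_stream)}")
    for (pair, actor, stream), g in df.groupby(["pair_id", "actor_id", "stream"]):
        t = g["time_s"].to_numpy(dtype=float)
        dec = np.flatnonzero(np.diff(t) < 0)
        if len(dec):
            row = int(g.index[dec[0] + 1])
            raise ValueError(
                f"non-monotone time_s for pair {pair} actor {actor} "
                f"stream {stream!r} at row {row}")
    return df


def write_truth(truth: pd.DataFrame, path) -> None:
    truth.to_csv(path, index=False, float_format=_FLOAT_FMT)


def read_truth(path) -> pd.DataFrame:
    return pd.read_csv(path)


def trial_metadata(truth: pd.DataFrame) -> pd.DataFrame:
    """Operational per-trial metadata (what the task program logs),
    stripped of behavioural ground truth."""
    cols = ["pair", "trial", "initiator", "responder", "target_cube",
            "validity", "response_correct", "trial_start", "trial_end"]
    return truth[cols].copy()


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=_json_default) + "\n")


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, (np.bool_,)):
        return bool(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
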