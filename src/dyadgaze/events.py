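"""Event segmentation: pointing-movement onsets and AOI look sequences.

Point onset follows a velocity-threshold rule: the earliest sample at
which the hand's speed *toward the target* reaches 5 % of the trial's
maximum of that speed, restricted to the movement segment that actually
terminates at the target.  Gaze samples are labelled per frame and
run-length encoded into looks, with short-gap bridging and a minimum
dwell duration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .geometry import AoiLayout, classify_gaze_stream

__all__ = [
    "PointOnset",
    "LookEvent",
    "NoOnsetError",
    "detect_point_onset",
    "segment_looks",
    "align_streams",
]


class NoOnsetError(ValueError):
    """Raised when no target-directed movement onset exists in a trial."""


@dataclass(frozen=True)
class PointOnset:
    onset_t: float  # seconds
    peak_speed: float  # m/s, trial maximum of target-directed speed
    threshold_speed: float  # 0.05 * peak_speed
    onset_index: int

    def __post_init__(self):
        if not np.isclose(self.threshold_speed, 0.05 * self.peak_speed, rtol=1e-6):
            raise ValueError("threshold_speed must equal 5% of peak_speed")


@dataclass(frozen=True)
class LookEvent:
    actor: int
    aoi: str
    start_t: float
    end_t: float

    def __post_init__(self):
        if self.end_t <= self.start_t:
            raise ValueError("LookEvent requires end_t > start_t")

    @property
    def duration(self) -> float:
        return self.end_t - self.start_t

    def contains(self, t: float, closed_right: bool = True) -> bool:
        return self.start_t <= t and (t <= self.end_t if closed_right else t < self.end_t)


def _target_directed_speed(times, pos, target, smooth_window: int = 3,
                           mode: str = "projected"):
    """Speed toward the target per sample.

    Velocity by central differences, lightly smoothed with a centered
    ``smooth_window``-sample moving average (odd width, so the estimate
    carries no phase shift that would bias threshold-crossing times);
    the target-directed speed is the projection of the velocity onto
    the instantaneous fingertip->target direction
    (``mode='projected'``), or the plain speed magnitude
    (``mode='magnitude'``).
    """
    vel = np.gradient(pos, times, axis=0)
    if smooth_window > 1:
        if smooth_window % 2 == 0:
            raise ValueError("smooth_window must be odd (centered window)")
        kernel = np.ones(smooth_window) / smooth_window
        vel = np.column_stack([np.convolve(vel[:, k], kernel, mode="same") for k in range(3)])
    if mode == "magnitude":
        return np.linalg.norm(vel, axis=1)
    to_target = target[None, :] - pos
    norms = np.linalg.norm(to_target, axis=1)
    unit = np.where(norms[:, None] > 1e-9, to_target / np.maximum(norms[:, None], 1e-12), 0.0)
    return np.einsum("ij,ij->i", vel, unit)


def detect_point_onset(times, positions, target, fraction: float = 0.05,
                       speed_mode: str = "projected",
                       arrival_radius: float = 0.10) -> PointOnset:
    """Detect the pointing-movement onset within one trial.

    Parameters
    ----------
    times, positions : (N,), (N, 3) arrays
        Fingertip samples on the native hand-tracking grid.
    target : (3,) array
        Pointed-at cube centre.
    fraction : float
        Onset threshold as a fraction of the trial's peak target-directed
        speed (default 0.05).
    speed_mode : {'projected', 'magnitude'}
        Whether speed is the velocity component toward the target or the
        plain magnitude.
    arrival_radius : float
        A movement segment "terminates at the target" when its final
        position is within this distance of the target (metres).

    Raises
    ------
    NoOnsetError
        If the hand never moves toward the target.
    ValueError
        On NaN samples (the message names the first offending index).
    """
    t = np.asarray(times, dtype=float)
    p = np.asarray(positions, dtype=float)
    tgt = np.asarray(target, dtype=float)
    if len(t) < 3:
        raise ValueError("need at least 3 samples to estimate speed")
    bad = ~np.isfinite(p).all(axis=1) | ~np.isfinite(t)
    if bad.any():
        raise ValueError(f"NaN/invalid hand sample at index {int(np.argmax(bad))}")
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")

    speed = _target_directed_speed(t, p, tgt, mode=speed_mode)
    peak = float(np.max(speed))
    if peak <= 1e-9:
        raise NoOnsetError("no movement toward the target in this trial")
    thr = fraction * peak

    above = speed >= thr
    # contiguous above-threshold segments; keep those that terminate at the
    # target, i.e. whose final above-threshold sample is followed by an
    # arrival within `arrival_radius`
    idx = np.flatnonzero(above)
    splits = np.flatnonzero(np.diff(idx) > 1)
    segments = np.split(idx, splits + 1)
    dist_end = np.linalg.norm(p - tgt, axis=1)
    candidates = []
    for seg in segments:
        # position once this movement has played out (end of segment onward)
        after = dist_end[seg[-1]:]
        if np.min(after) <= arrival_radius:
            candidates.append(seg)
    if not candidates:
        raise NoOnsetError("no movement segment terminates at the target")
    # earliest crossing belonging to a target-terminating segment
    onset_idx = int(candidates[0][0])
    return PointOnset(onset_t=float(t[onset_idx]), peak_speed=peak,
                      threshold_speed=thr, onset_index=onset_idx)


def segment_looks(times, labels, actor: int = 0, valid=None,
                  min_look_duration: float = 0.05,
                  gap_bridge: float = 0.05) -> list[LookEvent]:
    """Run-length encode per-sample AOI labels into look events.

    ``other`` runs shorter than ``gap_bridge`` flanked by two runs of
    one same AOI are relabelled to that AOI (bridging a blink-like
    dropout); genuine short looks at a *different* AOI are never
    bridged over.  After merging, runs shorter than
    ``min_look_duration`` are dropped.  ``other`` runs and
    invalid-tracking samples never form looks, and an invalid sample
    never bridges.
    """
    t = np.asarray(times, dtype=float)
    lab = np.asarray(labels, dtype=object).copy()
    if len(t) == 0:
        return []
    if np.any(np.diff(t) <= 0):
        raise ValueError("timestamps must be strictly increasing")
    if valid is not None:
        lab[~np.asarray(valid, dtype=bool)] = "__invalid__"
    dt = float(np.median(np.diff(t))) if len(t) > 1 else 0.0

    runs = _rle(lab)
    # gap bridging: a short interior run between two same-labelled runs
    changed = True
    while changed:
        changed = False
        for i in range(1, len(runs) - 1):
            s, e, label = runs[i]
            prev_lab = runs[i - 1][2]
            next_lab = runs[i + 1][2]
            dur = t[e - 1] + dt - t[s]
            if (label == "other" and prev_lab == next_lab
                    and prev_lab not in ("other", "__invalid__")
                    and dur <= gap_bridge + 1e-12):
                runs[i] = (s, e, prev_lab)
                changed = True
        if changed:
            runs = _merge_runs(runs)

    events = []
    for s, e, label in runs:
        if label in ("other", "__invalid__"):
            continue
        start_t = float(t[s])
        end_t = float(t[e - 1] + dt)
        if end_t - start_t + 1e-12 >= min_look_duration:
            events.append(LookEvent(actor=actor, aoi=str(label), start_t=start_t, end_t=end_t))
    return events


def _rle(labels):
    runs = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            runs.append((start, i, labels[start]))
            start = i
    return runs


def _merge_runs(runs):
    merged = [runs[0]]
    for s, e, label in runs[1:]:
        ps, pe, plab = merged[-1]
        if label == plab:
            merged[-1] = (ps, e, plab)
        else:
            merged.append((s, e, label))
    return merged


def segment_gaze_trial(gaze: pd.DataFrame, layout: AoiLayout, actor: int,
                       min_look_duration: float = 0.05,
                       gap_bridge: float = 0.05) -> list[LookEvent]:
    """Classify one actor's gaze samples for a trial and segment into looks."""
    origins = gaze[["origin_x", "origin_y", "origin_z"]].to_numpy()
    dirs = gaze[["dir_x", "dir_y", "dir_z"]].to_numpy()
    valid = gaze["validity"].to_numpy() >= 0.5
    labels = classify_gaze_stream(origins, dirs, layout, valid=valid)
    return segment_looks(gaze["time_s"].to_numpy(), labels, actor=actor, valid=valid,
                         min_look_duration=min_look_duration, gap_bridge=gap_bridge)


def align_streams(gaze: pd.DataFrame, hand: pd.DataFrame) -> pd.DataFrame:
    """Interpolate hand positions onto the gaze timestamps.

    Onset detection always runs on the native hand stream; this aligned
    view exists for AOI logic that needs the partner's hand pose at gaze
    sample times.  Linear interpolation; exact for linear motion.
    """
    tg = gaze["time_s"].to_numpy(dtype=float)
    th = hand["time_s"].to_numpy(dtype=float)
    if np.any(np.diff(tg) <= 0) or np.any(np.diff(th) <= 0):
        raise ValueError("timestamps must be strictly increasing in both streams")
    if tg[-1] < th[0] or th[-1] < tg[0]:
        raise ValueError("gaze and hand streams do not overlap in time")
    out = gaze.copy()
    for col in ("pos_x", "pos_y", "pos_z"):
        out[col] = np.interp(tg, th, hand[col].to_numpy(dtype=float))
    return out
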