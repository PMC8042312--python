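"""Scanpaths: fixation/saccade event sequences and their CSV format.

A scanpath is the event-level view of gaze: an ordered list of fixations
(position, onset, duration) whose consecutive pairs imply saccades
(amplitude, direction, duration).  Two classifiers convert raw
trajectories into scanpaths:

* :func:`classify_events` — a velocity-threshold (I-VT) segmentation
  operating on any uniformly sampled trajectory.  Fixations are defined
  functionally: periods during which a static or moderately moving patch
  is gazed at, so slow pursuit-like drift stays inside a fixation and
  only fast relocations become saccades.
* :func:`oracle_events` — available for simulated trajectories only; it
  reads the simulator's regime labels directly (exploitation runs become
  fixations, relocations become saccades), giving a classifier-free
  ground truth for downstream metric tests.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Scanpath", "classify_events", "oracle_events", "read_scanpath", "write_scanpath"]


@dataclass
class Scanpath:
    """Ordered fixations; saccades are the implied connectors.

    Arrays ``x``, ``y`` (px), ``onset`` and ``duration`` (s) are aligned
    per fixation.  Saccade *i* connects fixation *i* to fixation *i+1*;
    its duration is the onset gap minus the first fixation's duration.
    """

    x: np.ndarray
    y: np.ndarray
    onset: np.ndarray
    duration: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("x", "y", "onset", "duration"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.x)
        if not all(len(getattr(self, a)) == n for a in ("y", "onset", "duration")):
            raise ValueError("fixation columns must have equal length")
        if n:
            if np.any(self.duration <= 0):
                raise ValueError("fixation durations must be positive")
            if np.any(np.diff(self.onset) <= 0):
                raise ValueError("fixations must be temporally ordered")
            ends = self.onset[:-1] + self.duration[:-1]
            if np.any(ends > self.onset[1:] + 1e-9):
                raise ValueError("fixations must not overlap")

    @property
    def n_fixations(self) -> int:
        return len(self.x)

    @property
    def positions(self) -> np.ndarray:
        return np.stack([self.x, self.y], axis=1)

    # Saccade views -----------------------------------------------------

    @property
    def saccade_vectors(self) -> np.ndarray:
        """(n-1, 2) displacement vectors between consecutive fixations."""
        return np.diff(self.positions, axis=0)

    @property
    def saccade_amplitudes(self) -> np.ndarray:
        return np.linalg.norm(self.saccade_vectors, axis=1)

    @property
    def saccade_directions(self) -> np.ndarray:
        v = self.saccade_vectors
        return np.arctan2(v[:, 1], v[:, 0])

    @property
    def saccade_durations(self) -> np.ndarray:
        return self.onset[1:] - (self.onset[:-1] + self.duration[:-1])


def classify_events(
    trajectory,
    vel_threshold_px_s: float | None = None,
    min_fix_dur_s: float = 0.05,
) -> Scanpath:
    """I-VT segmentation of a uniformly sampled trajectory.

    Inter-sample speeds below the threshold are fixation intervals, runs
    above it saccades.  Candidate fixations shorter than
    ``min_fix_dur_s`` are absorbed into the surrounding saccade.  The
    default threshold is 5% of the frame diagonal per second (requires
    ``frame_w``/``frame_h`` in the trajectory meta), low enough to retain
    pursuit-like slow drift as fixation.
    """
    n = len(trajectory.t)
    if n < 2:
        raise ValueError("need at least 2 samples to classify events")
    dts = np.diff(trajectory.t)
    dt = dts[0]
    if np.any(dts <= 0) or not np.allclose(dts, dt, rtol=1e-6):
        raise ValueError("trajectory must be uniformly sampled")
    if vel_threshold_px_s is None:
        try:
            diag = float(np.hypot(trajectory.meta["frame_w"], trajectory.meta["frame_h"]))
        except (AttributeError, KeyError, TypeError) as exc:
            raise ValueError(
                "no velocity threshold given and frame size missing from meta"
            ) from exc
        vel_threshold_px_s = 0.05 * diag

    pos = np.stack([np.asarray(trajectory.x, float), np.asarray(trajectory.y, float)], axis=1)
    speed = np.linalg.norm(np.diff(pos, axis=0), axis=1) / dt
    is_fix = speed < vel_threshold_px_s  # one label per inter-sample interval

    # discard fixation runs shorter than the minimum duration
    min_len = max(int(np.ceil(min_fix_dur_s / dt)), 1)
    labels = is_fix.copy()
    runs = _runs(labels)
    for start, stop, val in runs:
        if val and (stop - start) < min_len:
            labels[start:stop] = False

    xs, ys, onsets, durs = [], [], [], []
    for start, stop, val in _runs(labels):
        if not val:
            continue
        members = pos[start : stop + 1]  # samples bounding the fixation intervals
        xs.append(members[:, 0].mean())
        ys.append(members[:, 1].mean())
        onsets.append(trajectory.t[start])
        durs.append((stop - start) * dt)
    meta = dict(getattr(trajectory, "meta", {}) or {})
    meta["classifier"] = "ivt"
    return Scanpath(
        x=np.array(xs), y=np.array(ys), onset=np.array(onsets), duration=np.array(durs),
        meta=meta,
    )


def oracle_events(trajectory) -> Scanpath:
    """Regime-label segmentation: one fixation per maximal exploitation run."""
    regime = np.asarray(getattr(trajectory, "regime", None))
    if regime is None or regime.dtype == object or len(regime) == 0:
        raise ValueError("trajectory carries no regime labels")
    t = np.asarray(trajectory.t, float)
    dt = float(t[1] - t[0]) if len(t) >= 2 else 0.0
    pos = np.stack([np.asarray(trajectory.x, float), np.asarray(trajectory.y, float)], axis=1)
    xs, ys, onsets, durs = [], [], [], []
    for start, stop, val in _runs(regime == 0):
        if not val:
            continue
        members = pos[start:stop]
        xs.append(members[:, 0].mean())
        ys.append(members[:, 1].mean())
        onsets.append(t[start])
        durs.append((stop - start) * dt)
    meta = dict(getattr(trajectory, "meta", {}) or {})
    meta["classifier"] = "oracle"
    return Scanpath(
        x=np.array(xs), y=np.array(ys), onset=np.array(onsets), duration=np.array(durs),
        meta=meta,
    )


def _runs(mask: np.ndarray):
    """Maximal constant runs of a boolean array as (start, stop, value)."""
    mask = np.asarray(mask)
    if len(mask) == 0:
        return []
    change = np.flatnonzero(np.diff(mask)) + 1
    starts = np.concatenate([[0], change])
    stops = np.concatenate([change, [len(mask)]])
    return [(int(a), int(b), bool(mask[a])) for a, b in zip(starts, stops)]


_COLUMNS = ["x", "y", "onset_s", "duration_s"]


def write_scanpath(scanpath: Scanpath, path) -> None:
    """Write the CSV dialect: columns x, y, onset_s, duration_s (+ meta extras)."""
    df = pd.DataFrame(
        {
            "x": scanpath.x,
            "y": scanpath.y,
            "onset_s": scanpath.onset,
            "duration_s": scanpath.duration,
        }
    )
    for key in ("observer", "clip"):
        if key in scanpath.meta:
            df[key] = scanpath.meta[key]
    df.to_csv(path, index=False)


def read_scanpath(path, meta: dict | None = None) -> Scanpath:
    """Read the scanpath CSV dialect; errors report the offending line."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty scanpath file") from exc
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        warnings.warn(f"{path}: header-only scanpath file, returning empty scanpath")
    for col in _COLUMNS:
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna() | df[col].isna()
        if bad.any():
            line = int(np.flatnonzero(bad.to_numpy())[0]) + 2  # 1-based + header
            raise ValueError(f"{path}: malformed value in column {col!r} at line {line}")
    out_meta = dict(meta or {})
    for key in ("observer", "clip"):
        if key in df.columns and len(df):
            out_meta[key] = df[key].iloc[0]
    return Scanpath(
        x=df["x"].to_numpy(float),
        y=df["y"].to_numpy(float),
        onset=df["onset_s"].to_numpy(float),
        duration=df["duration_s"].to_numpy(float),
        meta=out_meta,
    )
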