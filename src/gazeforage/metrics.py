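"""Scanpath similarity metrics: ScanMatch and MultiMatch.

ScanMatch discretizes a scanpath into a letter sequence — each fixation
maps to its spatial bin on a 14x8 grid and is repeated once per 50 ms of
duration — and scores two sequences by a Needleman-Wunsch global
alignment whose substitution score decreases with the distance between
bin centers.  Scores are normalized to [0, 1] with identical sequences
scoring exactly 1.

MultiMatch represents scanpaths as sequences of saccade vectors, aligns
the two sequences by dynamic programming on the pairwise vector-difference
matrix, and reports five similarity dimensions per aligned pair average:
shape, direction, length, position and duration.  No simplification
(direction/length/duration grouping) is applied.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .scanpath import Scanpath

__all__ = [
    "SMConfig",
    "MMScores",
    "encode_scanmatch",
    "scanmatch_score",
    "multimatch",
    "evaluate",
]


@dataclass(frozen=True)
class SMConfig:
    """ScanMatch settings: 14x8 spatial bins, 50 ms temporal bin, zero gap.

    The substitution score between two bin symbols is
    ``max_bin_distance - d(bin centers)`` in bin units, so identical bins
    score highest and the most distant corners score 0; the gap penalty
    defaults to 0.
    """

    n_bins_x: int = 14
    n_bins_y: int = 8
    t_bin_s: float = 0.05
    gap_penalty: float = 0.0

    def __post_init__(self) -> None:
        if self.n_bins_x < 1 or self.n_bins_y < 1:
            raise ValueError("bin counts must be >= 1")
        if self.t_bin_s <= 0:
            raise ValueError("t_bin_s must be positive")

    @property
    def n_symbols(self) -> int:
        return self.n_bins_x * self.n_bins_y

    def substitution_matrix(self) -> np.ndarray:
        """(n_symbols, n_symbols) substitution scores; max on the diagonal."""
        ix, iy = np.meshgrid(np.arange(self.n_bins_x), np.arange(self.n_bins_y))
        centers = np.stack([ix.ravel() + 0.5, iy.ravel() + 0.5], axis=1)
        # symbol index = iy * n_bins_x + ix
        order = np.argsort(iy.ravel() * self.n_bins_x + ix.ravel())
        centers = centers[order]
        d = np.linalg.norm(centers[:, None, :] - centers[None, :, :], axis=-1)
        return d.max() - d

    @property
    def max_substitution(self) -> float:
        return float(
            np.hypot(self.n_bins_x - 1, self.n_bins_y - 1)
        )


from functools import lru_cache


@lru_cache(maxsize=8)
def _cached_substitution(cfg: SMConfig) -> np.ndarray:
    return cfg.substitution_matrix()


def _round_half_away(x: np.ndarray) -> np.ndarray:
    """round() with halves away from zero (0.5 -> 1), unlike banker's rounding."""
    return np.sign(x) * np.floor(np.abs(x) + 0.5)


def encode_scanmatch(
    scanpath: Scanpath,
    frame_w: float,
    frame_h: float,
    cfg: SMConfig | None = None,
) -> np.ndarray:
    """Encode a scanpath as an integer symbol sequence.

    Each fixation maps to the symbol of its spatial bin and is repeated
    ``round(duration / t_bin)`` times (at least once).  Fixations must lie
    within the frame after clamping.
    """
    cfg = cfg or SMConfig()
    x, y = scanpath.x, scanpath.y
    if np.any((x < 0) | (x > frame_w) | (y < 0) | (y > frame_h)):
        raise ValueError("fixation outside the frame; clamp or check frame size")
    ix = np.minimum((x / frame_w * cfg.n_bins_x).astype(int), cfg.n_bins_x - 1)
    iy = np.minimum((y / frame_h * cfg.n_bins_y).astype(int), cfg.n_bins_y - 1)
    symbols = iy * cfg.n_bins_x + ix
    reps = np.maximum(_round_half_away(scanpath.duration / cfg.t_bin_s), 1).astype(int)
    return np.repeat(symbols, reps)


def _nw_score(seq_a: np.ndarray, seq_b: np.ndarray, sub: np.ndarray, gap: float) -> float:
    """Needleman-Wunsch maximal global alignment score (linear gap penalty).

    Row-vectorized: the within-row left-to-right dependency
    ``M[i,j] = max(candidate[j], M[i,j-1] + gap)`` is a max-plus prefix
    scan, computed with ``maximum.accumulate`` on gap-detrended values.
    """
    n, m = len(seq_a), len(seq_b)
    j_idx = np.arange(m + 1)
    sub_rows = sub[seq_a]  # (n, m) substitution scores against seq_b
    sub_rows = sub_rows[:, seq_b]
    prev = j_idx * gap
    buf = np.empty(m + 1)
    if gap == 0.0:
        for i in range(n):
            np.maximum(prev[:-1] + sub_rows[i], prev[1:], out=buf[1:])
            buf[0] = 0.0
            np.maximum.accumulate(buf, out=prev)
    else:
        trend = j_idx * gap
        for i in range(n):
            np.maximum(prev[:-1] + sub_rows[i], prev[1:] + gap, out=buf[1:])
            buf[1:] -= trend[1:]
            buf[0] = (i + 1) * gap
            np.maximum.accumulate(buf, out=prev)
            prev += trend
    return float(prev[-1])


def scanmatch_score(
    seq_a: Sequence[int],
    seq_b: Sequence[int],
    cfg: SMConfig | None = None,
) -> float:
    """Normalized ScanMatch similarity in [0, 1]; symmetric; 1 iff optimal
    alignment matches every symbol of the longer sequence at full score."""
    cfg = cfg or SMConfig()
    a = np.asarray(seq_a, dtype=int)
    b = np.asarray(seq_b, dtype=int)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("symbol sequences must be non-empty")
    if a.min() < 0 or b.min() < 0 or a.max() >= cfg.n_symbols or b.max() >= cfg.n_symbols:
        raise ValueError("symbols out of range for the configured bins")
    sub = _cached_substitution(cfg)
    score = _nw_score(a, b, sub, cfg.gap_penalty)
    return score / (cfg.max_substitution * max(len(a), len(b)))


@dataclass(frozen=True)
class MMScores:
    """MultiMatch similarity per dimension, each in [0, 1]."""

    shape: float
    direction: float
    length: float
    position: float
    duration: float

    def __post_init__(self) -> None:
        for name in ("shape", "direction", "length", "position", "duration"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} score {v} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "MM_shape": self.shape,
            "MM_dir": self.direction,
            "MM_len": self.length,
            "MM_pos": self.position,
            "MM_dur": self.duration,
        }


def _align_vectors(u: np.ndarray, v: np.ndarray) -> list[tuple[int, int]]:
    """Min-cost monotone alignment of two saccade-vector sequences.

    Dynamic programming over the pairwise vector-difference matrix with
    diagonal/right/down moves; returns the aligned index pairs along the
    optimal path from (0, 0) to (I-1, J-1).
    """
    cost = np.linalg.norm(u[:, None, :] - v[None, :, :], axis=-1)
    n, m = cost.shape
    acc = np.full((n, m), np.inf)
    move = np.zeros((n, m), dtype=np.int8)  # 0 diag, 1 up(i-1), 2 left(j-1)
    acc[0, 0] = cost[0, 0]
    for j in range(1, m):
        acc[0, j] = acc[0, j - 1] + cost[0, j]
        move[0, j] = 2
    for i in range(1, n):
        acc[i, 0] = acc[i - 1, 0] + cost[i, 0]
        move[i, 0] = 1
        diag = acc[i - 1, :-1]
        up = acc[i - 1, 1:]
        best = np.minimum(diag, up)
        mv = np.where(diag <= up, 0, 1).astype(np.int8)
        # left dependency resolved sequentially
        for j in range(1, m):
            left = acc[i, j - 1]
            if left < best[j - 1]:
                acc[i, j] = left + cost[i, j]
                move[i, j] = 2
            else:
                acc[i, j] = best[j - 1] + cost[i, j]
                move[i, j] = mv[j - 1]
    pairs = []
    i, j = n - 1, m - 1
    while True:
        pairs.append((i, j))
        if i == 0 and j == 0:
            break
        mv = move[i, j]
        if mv == 0:
            i, j = i - 1, j - 1
        elif mv == 1:
            i -= 1
        else:
            j -= 1
    return pairs[::-1]


def _angle_diff(a: float, b: float) -> float:
    d = abs(a - b) % (2 * np.pi)
    return min(d, 2 * np.pi - d)


def multimatch(scan_a: Scanpath, scan_b: Scanpath, frame_w: float, frame_h: float) -> MMScores:
    """Five-dimensional MultiMatch similarity between two scanpaths.

    Requires at least two fixations (one saccade vector) per path.  Per
    aligned saccade pair (u, v) the dissimilarities are

    * shape: |u - v| / (2 diag)
    * length: ||u| - |v|| / diag
    * direction: angular difference / pi (0 for zero-length vectors)
    * position: distance between the source fixations / diag
    * duration: |d_u - d_v| / max(d_u, d_v), d the source fixation durations

    and each similarity is 1 minus the mean dissimilarity over the path.
    """
    for sp in (scan_a, scan_b):
        if sp.n_fixations < 2:
            raise ValueError("multimatch requires at least 2 fixations per scanpath")
    diag = float(np.hypot(frame_w, frame_h))
    u, v = scan_a.saccade_vectors, scan_b.saccade_vectors
    pairs = _align_vectors(u, v)

    shape_d, len_d, dir_d, pos_d, dur_d = [], [], [], [], []
    for i, j in pairs:
        ui, vj = u[i], v[j]
        shape_d.append(np.linalg.norm(ui - vj) / (2 * diag))
        len_d.append(abs(np.linalg.norm(ui) - np.linalg.norm(vj)) / diag)
        if np.linalg.norm(ui) == 0 or np.linalg.norm(vj) == 0:
            dir_d.append(0.0)
        else:
            dir_d.append(
                _angle_diff(np.arctan2(ui[1], ui[0]), np.arctan2(vj[1], vj[0])) / np.pi
            )
        pos_d.append(np.linalg.norm(scan_a.positions[i] - scan_b.positions[j]) / diag)
        da, db = scan_a.duration[i], scan_b.duration[j]
        dur_d.append(abs(da - db) / max(da, db))
    clamp = lambda x: float(min(max(x, 0.0), 1.0))  # noqa: E731
    return MMScores(
        shape=clamp(1 - np.mean(shape_d)),
        direction=clamp(1 - np.mean(dir_d)),
        length=clamp(1 - np.mean(len_d)),
        position=clamp(1 - np.mean(pos_d)),
        duration=clamp(1 - np.mean(dur_d)),
    )


def _pair_scores(sp_a: Scanpath, sp_b: Scanpath, frame_w, frame_h, cfg: SMConfig) -> dict:
    sm = scanmatch_score(
        encode_scanmatch(sp_a, frame_w, frame_h, cfg),
        encode_scanmatch(sp_b, frame_w, frame_h, cfg),
        cfg,
    )
    mm = multimatch(sp_a, sp_b, frame_w, frame_h)
    return {"SM": sm, **mm.as_dict()}


SCORE_COLUMNS = ["SM", "MM_shape", "MM_dir", "MM_len", "MM_pos", "MM_dur"]


def evaluate(
    real_by_clip: Mapping[str, Sequence[Scanpath]],
    models: Mapping[str, Mapping[str, Sequence[Scanpath]]],
    frame_w: float,
    frame_h: float,
    cfg: SMConfig | None = None,
) -> pd.DataFrame:
    """Per-clip mean similarity scores, Real-vs-Real and Real-vs-Model.

    ``real_by_clip`` maps clip id to the human (or reference) scanpaths;
    ``models`` maps model name to its own clip->scanpaths mapping.  For
    each clip the Real row averages scores over all unordered real pairs
    and each model row averages over all real x model pairs.  Returns a
    tidy frame with columns clip, model, SM, MM_shape, MM_dir, MM_len,
    MM_pos, MM_dur.
    """
    cfg = cfg or SMConfig()
    rows = []
    for clip, real in real_by_clip.items():
        if len(real) < 2:
            raise ValueError(f"clip {clip!r}: need >= 2 real scanpaths")
        rr = [
            _pair_scores(a, b, frame_w, frame_h, cfg) for a, b in combinations(real, 2)
        ]
        rows.append({"clip": clip, "model": "Real", **pd.DataFrame(rr).mean().to_dict()})
        for name, by_clip in models.items():
            model_paths = by_clip[clip]
            if len(model_paths) == 0:
                raise ValueError(f"model {name!r} has no scanpaths for clip {clip!r}")
            rm = [
                _pair_scores(a, b, frame_w, frame_h, cfg)
                for a in real
                for b in model_paths
            ]
            rows.append({"clip": clip, "model": name, **pd.DataFrame(rm).mean().to_dict()})
    return pd.DataFrame(rows, columns=["clip", "model", *SCORE_COLUMNS])
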