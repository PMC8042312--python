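"""Patch landscapes: the time-varying ensemble of audio-visual gaze attractors.

A *patch* is a spatially localized region of gaze attraction (a speaking
face, a listener's face, a hand gesture, the screen center) modeled as a
2-D Gaussian with center ``mu`` (pixels), covariance ``sigma`` (pixels²)
and a nonnegative social value ``value``.  A *landscape* is the
frame-indexed collection of patches present in a clip, together with the
frame geometry.

The module also provides a synthetic conversational-scene generator so the
whole simulation/evaluation pipeline runs without any video input: a
handful of faces taking speaking turns, occasional gesture patches tied to
the current speaker, and a broad center-bias patch.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PatchClass",
    "Patch",
    "Landscape",
    "ValueMap",
    "DEFAULT_VALUE_MAP",
    "SceneSpec",
    "assign_values",
    "generate_scene",
]


class PatchClass(str, Enum):
    """Semantic category of a patch; drives its prior value."""

    SPEAKER = "speaker"
    FACE = "face"
    GESTURE = "gesture"
    CENTER_BIAS = "center_bias"
    OTHER = "other"


@dataclass(frozen=True)
class Patch:
    """A 2-D Gaussian gaze attractor.

    Parameters
    ----------
    id : int
        Stable identifier, persistent across frames while the patch exists.
    klass : PatchClass
        Semantic category (speaker, face, gesture, center_bias, other).
    mu : ndarray, shape (2,)
        Center in pixels, origin top-left, x rightward, y downward.
    sigma : ndarray, shape (2, 2)
        Symmetric positive-definite covariance, pixels².
    value : float
        Nonnegative social value V_p; 0.0 until assigned.
    """

    id: int
    klass: PatchClass
    mu: np.ndarray
    sigma: np.ndarray
    value: float = 0.0

    def __post_init__(self) -> None:
        mu = np.asarray(self.mu, dtype=float).reshape(2)
        sigma = np.asarray(self.sigma, dtype=float).reshape(2, 2)
        object.__setattr__(self, "mu", mu)
        object.__setattr__(self, "sigma", sigma)
        object.__setattr__(self, "klass", PatchClass(self.klass))
        if abs(sigma[0, 1] - sigma[1, 0]) > 1e-9 * max(abs(sigma[0, 1]), 1.0):
            raise ValueError(f"patch {self.id}: covariance must be symmetric")
        # 2x2 symmetric PD iff leading element and determinant are positive
        det = sigma[0, 0] * sigma[1, 1] - sigma[0, 1] * sigma[1, 0]
        if sigma[0, 0] <= 0 or det <= 0:
            raise ValueError(f"patch {self.id}: covariance must be positive definite")
        if self.value < 0:
            raise ValueError(f"patch {self.id}: value must be >= 0")

    @property
    def width(self) -> np.ndarray:
        """Per-axis standard deviation (sqrt of the covariance diagonal), px."""
        return np.sqrt(np.diag(self.sigma))


Frame = Sequence[Patch]


@dataclass
class Landscape:
    """Frame-indexed ensemble of patches plus frame geometry.

    ``frames[k]`` lists the patches visible during video frame *k*; patch
    identity across frames is by the ``id`` field.  Between video frames
    the landscape is held constant (zero-order hold), so ``frame_at(t)``
    returns the frame whose interval contains ``t``.
    """

    frame_w: float
    frame_h: float
    fps: float
    frames: list[list[Patch]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.fps <= 0:
            raise ValueError("fps must be positive")
        for k, frame in enumerate(self.frames):
            if len(frame) == 0:
                raise ValueError(f"frame {k} is empty; every frame needs >= 1 patch")

    @property
    def diag(self) -> float:
        """Frame diagonal in pixels; the spatial normalization unit."""
        return float(np.hypot(self.frame_w, self.frame_h))

    @property
    def center(self) -> np.ndarray:
        return np.array([self.frame_w / 2.0, self.frame_h / 2.0])

    @property
    def n_frames(self) -> int:
        return len(self.frames)

    @property
    def duration(self) -> float:
        """Clip duration in seconds."""
        return len(self.frames) / self.fps

    def frame_at(self, t: float) -> list[Patch]:
        """Patches visible at time ``t`` seconds (zero-order hold)."""
        if t < 0:
            raise ValueError("t must be >= 0")
        k = min(int(t * self.fps), len(self.frames) - 1)
        return self.frames[k]

    # ------------------------------------------------------------------ I/O

    def to_json(self, path) -> None:
        payload = {
            "frame_w": self.frame_w,
            "frame_h": self.frame_h,
            "fps": self.fps,
            "frames": [
                [
                    {
                        "id": p.id,
                        "klass": p.klass.value,
                        "mu": p.mu.tolist(),
                        "sigma": p.sigma.tolist(),
                        "value": p.value,
                    }
                    for p in frame
                ]
                for frame in self.frames
            ],
        }
        with open(path, "w") as fh:
            json.dump(payload, fh)

    @classmethod
    def from_json(cls, path) -> "Landscape":
        with open(path) as fh:
            payload = json.load(fh)
        frames = [
            [
                Patch(
                    id=int(p["id"]),
                    klass=PatchClass(p["klass"]),
                    mu=np.asarray(p["mu"], dtype=float),
                    sigma=np.asarray(p["sigma"], dtype=float),
                    value=float(p.get("value", 0.0)),
                )
                for p in frame
            ]
            for frame in payload["frames"]
        ]
        return cls(
            frame_w=float(payload["frame_w"]),
            frame_h=float(payload["frame_h"]),
            fps=float(payload["fps"]),
            frames=frames,
        )

    def to_csv(self, path) -> None:
        """Flat dialect: frame, id, klass, mu_x, mu_y, s_xx, s_xy, s_yy, value."""
        rows = []
        for k, frame in enumerate(self.frames):
            for p in frame:
                rows.append(
                    {
                        "frame": k,
                        "id": p.id,
                        "klass": p.klass.value,
                        "mu_x": p.mu[0],
                        "mu_y": p.mu[1],
                        "s_xx": p.sigma[0, 0],
                        "s_xy": p.sigma[0, 1],
                        "s_yy": p.sigma[1, 1],
                        "value": p.value,
                    }
                )
        pd.DataFrame(rows).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, frame_w: float, frame_h: float, fps: float) -> "Landscape":
        df = pd.read_csv(path)
        frames: list[list[Patch]] = []
        for k in range(int(df["frame"].max()) + 1):
            sub = df[df["frame"] == k]
            frames.append(
                [
                    Patch(
                        id=int(r.id),
                        klass=PatchClass(r.klass),
                        mu=np.array([r.mu_x, r.mu_y]),
                        sigma=np.array([[r.s_xx, r.s_xy], [r.s_xy, r.s_yy]]),
                        value=float(r.value),
                    )
                    for r in sub.itertuples()
                ]
            )
        return cls(frame_w=frame_w, frame_h=frame_h, fps=fps, frames=frames)


class ValueMap(dict):
    """Mapping from patch class to prior value in (0, 1].

    The speaker value must be strictly greatest: speaking faces are the
    most likely gaze target in conversational scenes, and the drift-rate
    construction relies on that ordering.
    """

    def __init__(self, mapping: Mapping[PatchClass | str, float]):
        items = {PatchClass(k): float(v) for k, v in mapping.items()}
        if not items:
            raise ValueError("value map must not be empty")
        for k, v in items.items():
            if v <= 0:
                raise ValueError(f"value for {k.value!r} must be positive, got {v}")
        if PatchClass.SPEAKER in items:
            others = [v for k, v in items.items() if k is not PatchClass.SPEAKER]
            if others and items[PatchClass.SPEAKER] <= max(others):
                raise ValueError("speaker value must be strictly greatest")
        super().__init__(items)


DEFAULT_VALUE_MAP = ValueMap(
    {
        PatchClass.SPEAKER: 0.5,
        PatchClass.FACE: 0.2,
        PatchClass.GESTURE: 0.15,
        PatchClass.CENTER_BIAS: 0.15,
    }
)


def assign_values(landscape: Landscape, value_map: Mapping) -> Landscape:
    """Return a copy of ``landscape`` with each patch valued by its class.

    Patch values are priors looked up purely from the patch type; a speaker
    patch receives the speaker prior, a listener face the face prior, and
    so on.  Raises ``KeyError`` naming the class if some patch class has no
    entry in ``value_map``.
    """
    vm = value_map if isinstance(value_map, ValueMap) else ValueMap(value_map)
    frames = []
    for k, frame in enumerate(landscape.frames):
        new_frame = []
        for p in frame:
            if p.klass not in vm:
                raise KeyError(
                    f"no value configured for patch class {p.klass.value!r} "
                    f"(frame {k}, patch {p.id})"
                )
            new_frame.append(replace(p, value=vm[p.klass]))
        frames.append(new_frame)
    return Landscape(
        frame_w=landscape.frame_w,
        frame_h=landscape.frame_h,
        fps=landscape.fps,
        frames=frames,
    )


# --------------------------------------------------------------------------
# Synthetic conversational scenes
# --------------------------------------------------------------------------


@dataclass
class SceneSpec:
    """Parameters of a synthetic conversational clip.

    Defaults emulate a ~20 s one-shot conversation at 1280x720: a few faces
    along a rough horizontal line, one of them speaking at any moment with
    speaker turns of ~5 s on average, occasional gesture patches attached
    to the current speaker, and one broad center-bias patch.  Patch centers
    drift by a bounded random walk (<= ``max_drift_px`` per frame) to mimic
    the limited head/hand motion of conversational footage.
    """

    duration_s: float = 20.0
    fps: float = 30.0
    frame_w: float = 1280.0
    frame_h: float = 720.0
    n_faces: int = 3
    mean_turn_s: float = 5.0
    min_turn_s: float = 1.0
    gesture_prob: float = 0.3
    max_drift_px: float = 2.0
    face_sd_min_px: float = 25.0
    face_sd_max_px: float = 50.0
    face_spacing_px: float = 230.0

    def __post_init__(self) -> None:
        if self.duration_s <= 0 or self.fps <= 0:
            raise ValueError("duration and fps must be positive")
        if not (2 <= self.n_faces <= 5):
            raise ValueError("n_faces must be between 2 and 5")
        if self.mean_turn_s <= self.min_turn_s:
            raise ValueError("mean_turn_s must exceed min_turn_s")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SceneSpec":
        return cls(**dict(d))


def _sample_turns(spec: SceneSpec, rng: np.random.Generator) -> list[tuple[float, int]]:
    """Speaker schedule as (turn_start_s, face_index) covering the clip.

    Turn lengths are shifted-exponential: ``min_turn_s`` plus an
    exponential with mean ``mean_turn_s - min_turn_s``, so the mean turn is
    ``mean_turn_s`` and degenerate sub-second turns cannot occur.
    Consecutive turns always change speaker.
    """
    turns: list[tuple[float, int]] = []
    t = 0.0
    current = int(rng.integers(spec.n_faces))
    while t < spec.duration_s:
        turns.append((t, current))
        t += spec.min_turn_s + rng.exponential(spec.mean_turn_s - spec.min_turn_s)
        nxt = int(rng.integers(spec.n_faces - 1))
        current = nxt if nxt < current else nxt + 1
    return turns


def generate_scene(
    spec: SceneSpec,
    seed: int | np.random.Generator,
    value_map: Mapping | None = None,
) -> Landscape:
    """Generate a synthetic conversational landscape.

    Deterministic under a fixed integer seed.  Every frame carries exactly
    one speaker patch (the face holding the current turn), the remaining
    faces as listener patches, one center-bias patch at the frame center,
    and — during turns that drew a gesture — one gesture patch near the
    speaker.  Values are assigned from ``value_map`` (default
    :data:`DEFAULT_VALUE_MAP`).
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    vm = DEFAULT_VALUE_MAP if value_map is None else value_map

    n_frames = int(round(spec.duration_s * spec.fps))
    margin = 3.0 * spec.face_sd_max_px

    # Faces clustered around the frame center along a horizontal band, as in
    # medium close-up conversational framing; covariances fixed per face for
    # the whole clip, mildly anisotropic (faces are taller than wide).
    offsets = (np.arange(spec.n_faces) - (spec.n_faces - 1) / 2.0) * spec.face_spacing_px
    xs = np.clip(spec.frame_w / 2.0 + offsets, margin, spec.frame_w - margin)
    mus = np.stack(
        [
            xs + rng.uniform(-30, 30, spec.n_faces),
            rng.uniform(0.38, 0.52, spec.n_faces) * spec.frame_h,
        ],
        axis=1,
    )
    sds = rng.uniform(spec.face_sd_min_px, spec.face_sd_max_px, (spec.n_faces, 2))
    sds[:, 1] *= 1.2  # vertical elongation
    sds = np.clip(sds, spec.face_sd_min_px, 1.2 * spec.face_sd_max_px)
    face_sigmas = [np.diag(sd**2) for sd in sds]

    turns = _sample_turns(spec, rng)
    turn_starts = np.array([t for t, _ in turns])
    turn_speakers = [f for _, f in turns]
    turn_has_gesture = rng.random(len(turns)) < spec.gesture_prob

    center_patch_sigma = np.diag(
        [(spec.frame_w / 6.0) ** 2, (spec.frame_h / 6.0) ** 2]
    )
    gesture_sd = 0.8 * spec.face_sd_max_px

    # Pre-draw per-frame drift steps for each face (bounded random walk).
    steps = rng.uniform(-spec.max_drift_px, spec.max_drift_px, (n_frames, spec.n_faces, 2))
    gesture_offsets = rng.uniform(-20, 20, (len(turns), 2)) + np.array([0.0, 120.0])

    frames: list[list[Patch]] = []
    face_mu = mus.copy()
    next_gesture_id = 1 + spec.n_faces
    gesture_ids = {}  # turn index -> patch id
    for k in range(n_frames):
        t = k / spec.fps
        turn_idx = int(np.searchsorted(turn_starts, t, side="right") - 1)
        speaker = turn_speakers[turn_idx]
        if k > 0:
            face_mu = face_mu + steps[k]
            face_mu[:, 0] = np.clip(face_mu[:, 0], margin, spec.frame_w - margin)
            face_mu[:, 1] = np.clip(face_mu[:, 1], margin, spec.frame_h - margin)
        frame: list[Patch] = [
            Patch(
                id=0,
                klass=PatchClass.CENTER_BIAS,
                mu=np.array([spec.frame_w / 2.0, spec.frame_h / 2.0]),
                sigma=center_patch_sigma,
            )
        ]
        for f in range(spec.n_faces):
            frame.append(
                Patch(
                    id=1 + f,
                    klass=PatchClass.SPEAKER if f == speaker else PatchClass.FACE,
                    mu=face_mu[f].copy(),
                    sigma=face_sigmas[f],
                )
            )
        if turn_has_gesture[turn_idx]:
            if turn_idx not in gesture_ids:
                gesture_ids[turn_idx] = next_gesture_id
                next_gesture_id += 1
            gmu = face_mu[speaker] + gesture_offsets[turn_idx]
            gmu = np.clip(
                gmu,
                [gesture_sd, gesture_sd],
                [spec.frame_w - gesture_sd, spec.frame_h - gesture_sd],
            )
            frame.append(
                Patch(
                    id=gesture_ids[turn_idx],
                    klass=PatchClass.GESTURE,
                    mu=gmu,
                    sigma=np.diag([gesture_sd**2, gesture_sd**2]),
                )
            )
        frames.append(frame)

    scene = Landscape(
        frame_w=spec.frame_w, frame_h=spec.frame_h, fps=spec.fps, frames=frames
    )
    return assign_values(scene, vm)
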