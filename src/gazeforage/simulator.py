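"""Orchestration of the patch cycle: race, relocate, exploit.

The simulator couples the decision race and the spatial O-U process on a
shared clock (default 60 Hz, the eye-tracker rate).  Starting at the
frame center, gaze first relocates to the nearest patch; from then on it
alternates

1. *exploitation* (s_t = 0): the O-U process wanders inside the current
   patch while the racers accumulate evidence; when a racer wins, either
   the current patch is confirmed (race restarts in place) or
2. *relocation* (s_t = 1): the race is paused and gaze sweeps toward the
   winning patch until it arrives (Mahalanobis criterion), after which a
   fresh race starts.

Also provides the center-biased Random baseline and cohort simulation of
many artificial observers.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from . import decision as dec
from . import spatial as sp
from .landscape import Landscape
from .scanpath import Scanpath

__all__ = ["Trajectory", "SimConfig", "simulate", "random_baseline", "run_cohort"]


@dataclass
class Trajectory:
    """Uniformly sampled gaze trajectory with regime and attractor labels.

    ``x``/``y`` are clamped to the frame; ``regime`` is 0 during
    exploitation and 1 during relocation; ``attractor`` is the patch id
    currently serving as the O-U mean.
    """

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    regime: np.ndarray
    attractor: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("x", "y", "regime", "attractor"):
            if len(getattr(self, name)) != n:
                raise ValueError("all sample columns must have equal length")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0) or not np.allclose(dt, dt[0], rtol=1e-6):
                raise ValueError("t must be strictly increasing and uniformly spaced")

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) >= 2 else float("nan")

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) >= 2 else 0.0

    def to_csv(self, path, sidecar: bool = True) -> None:
        pd.DataFrame(
            {"t": self.t, "x": self.x, "y": self.y, "regime": self.regime,
             "attractor": self.attractor}
        ).to_csv(path, index=False)
        if sidecar:
            with open(str(path) + ".meta.json", "w") as fh:
                json.dump(self.meta, fh, default=str)

    @classmethod
    def from_csv(cls, path) -> "Trajectory":
        df = pd.read_csv(path)
        meta = {}
        try:
            with open(str(path) + ".meta.json") as fh:
                meta = json.load(fh)
        except FileNotFoundError:
            pass
        return cls(
            t=df["t"].to_numpy(float),
            x=df["x"].to_numpy(float),
            y=df["y"].to_numpy(float),
            regime=df["regime"].to_numpy(int),
            attractor=df["attractor"].to_numpy(int),
            meta=meta,
        )


@dataclass
class SimConfig:
    """Simulation configuration: decision + spatial parameters and run length."""

    decision: dec.DecisionParams = field(default_factory=dec.DecisionParams)
    spatial: sp.SpatialConfig = field(default_factory=sp.SpatialConfig)
    duration_s: float | None = None  # None: full landscape duration
    start: str = "center"  # or "point:x,y"
    seed: int = 0
    race_during_flight: bool = False

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimConfig":
        d = dict(d)
        if "decision" in d:
            d["decision"] = dec.DecisionParams.from_dict(d["decision"])
        if "spatial" in d:
            d["spatial"] = sp.SpatialConfig.from_dict(d["spatial"])
        return cls(**d)

    def params_hash(self) -> str:
        blob = json.dumps(
            {"decision": vars(self.decision), "spatial": vars(self.spatial),
             "duration_s": self.duration_s, "start": self.start,
             "race_during_flight": self.race_during_flight},
            sort_keys=True, default=str,
        )
        return hashlib.sha256(blob.encode()).hexdigest()[:12]


def _start_position(config: SimConfig, landscape: Landscape) -> np.ndarray:
    if config.start == "center":
        return landscape.center.copy()
    if config.start.startswith("point:"):
        x, y = (float(v) for v in config.start[len("point:"):].split(","))
        return np.array([x, y])
    raise ValueError(f"unknown start spec {config.start!r}")


def simulate(landscape: Landscape, config: SimConfig, seed: int | None = None) -> Trajectory:
    """Simulate one artificial observer watching ``landscape``.

    Deterministic under a fixed seed.  The master seed is split into
    independent streams for decision noise and spatial noise, so either
    component can be replayed in isolation.
    """
    if seed is None:
        seed = config.seed
    duration = config.duration_s if config.duration_s is not None else landscape.duration
    if duration > landscape.duration + 1e-9:
        raise ValueError(
            f"requested duration {duration} s exceeds landscape duration "
            f"{landscape.duration} s"
        )
    if not any(p.value > 0 for p in landscape.frames[0]):
        raise ValueError("landscape has no valued patches; call assign_values first")

    dec_rng, spa_rng = (
        np.random.default_rng(s) for s in np.random.SeedSequence(seed).spawn(2)
    )
    dparams, sconf = config.decision, config.spatial
    dt = dparams.dt
    sqrt_dt = np.sqrt(dt)
    diag = landscape.diag
    n_samples = int(round(duration / dt))

    r = _start_position(config, landscape)
    frame0 = landscape.frame_at(0.0)
    # initial attractor: nearest patch to the starting point (typically the
    # center-bias patch); the clip opens with a relocation toward it
    attractor = min(frame0, key=lambda p: np.linalg.norm(p.mu - r)).id
    regime = 1

    t_arr = np.arange(n_samples) * dt
    xs = np.empty(n_samples)
    ys = np.empty(n_samples)
    regimes = np.empty(n_samples, dtype=int)
    attrs = np.empty(n_samples, dtype=int)

    # race state as plain arrays (the hot loop equivalent of RaceState)
    q: np.ndarray | None = None
    t_on_patch = 0.0
    frame_idx = -1
    frame: list = []
    lookup: dict = {}
    ids: list[int] = []
    mus = vals = None
    ou: sp.OUParams | None = None  # cached while regime/frame/attractor stable
    for i in range(n_samples):
        k = min(int(t_arr[i] * landscape.fps), landscape.n_frames - 1)
        if k != frame_idx:  # zero-order hold between video frames
            frame_idx = k
            frame = landscape.frames[k]
            lookup = {p.id: p for p in frame}
            new_ids = [p.id for p in frame]
            if new_ids != ids:
                # vanished racers drop out, newcomers join with q = 0
                if q is not None:
                    old = dict(zip(ids, q))
                    q = np.array([old.get(pid, 0.0) for pid in new_ids])
                ids = new_ids
            mus = np.array([p.mu for p in frame])
            vals = np.array([p.value for p in frame])
            ou = None
        if attractor not in lookup:
            # attractor vanished (e.g. gesture ended): retarget nearest patch
            attractor = min(frame, key=lambda p: np.linalg.norm(p.mu - r)).id
            regime = 1
            q = None
            ou = None
        patch = lookup[attractor]

        xs[i] = min(max(r[0], 0.0), landscape.frame_w)
        ys[i] = min(max(r[1], 0.0), landscape.frame_h)
        regimes[i] = regime
        attrs[i] = attractor

        if ou is None or regime == 1:
            gstate = sp.GazeState(r=r, regime=regime, attractor=attractor, t=t_arr[i])
            ou = sp.ou_params_for(gstate, patch, frame, sconf, diag=diag)
            # precomputed exact-transition constants (see spatial.ou_step)
            ou_decay = np.exp(-ou.b * dt)
            if ou.noise == "exact":
                ou_sd = (ou.sigma / np.sqrt(2.0 * ou.b)) * np.sqrt(1.0 - ou_decay**2)
            else:
                ou_sd = ou.sigma * ou.b * (1.0 - ou_decay**2)
        r = r * ou_decay + patch.mu * (1.0 - ou_decay) + ou_sd * spa_rng.standard_normal(2)

        if regime == 1:
            if config.race_during_flight and q is not None:
                q = q + _drifts(ids, mus, vals, attractor, t_on_patch, dparams, diag) * dt \
                    + dparams.c * sqrt_dt * dec_rng.standard_normal(len(ids))
            if sp.has_arrived(r, patch, sconf.arrival_mahalanobis):
                regime = 0
                t_on_patch = 0.0
                q = np.zeros(len(ids))
                ou = None
        else:
            t_on_patch += dt
            if q is None:
                q = np.zeros(len(ids))
            # Euler step of the race SDE: q += I dt + c sqrt(dt) z
            q = q + _drifts(ids, mus, vals, attractor, t_on_patch, dparams, diag) * dt \
                + dparams.c * sqrt_dt * dec_rng.standard_normal(len(ids))
            if np.max(q) >= dparams.a:
                state = dec.RaceState(q=q, p_star=attractor, t_on_patch=t_on_patch,
                                      patch_ids=ids)
                winner = dec.check_threshold(state, dparams.a)
                if winner == attractor:
                    q = np.zeros(len(ids))
                else:
                    attractor = winner
                    regime = 1
                    q = None
                    ou = None

    return Trajectory(
        t=t_arr, x=xs, y=ys, regime=regimes, attractor=attrs,
        meta={
            "frame_w": landscape.frame_w, "frame_h": landscape.frame_h,
            "fps": landscape.fps, "sample_rate_hz": 1.0 / dt,
            "seed": int(seed), "params_hash": config.params_hash(),
        },
    )


def _drifts(ids, mus, vals, p_star, t_on_patch, dparams, diag):
    """Drift vector I_p = Psi * nu_p from precomputed per-frame arrays.

    Equivalent to :func:`gazeforage.decision.drift_rates`; kept in array
    form for the simulation hot loop.
    """
    i_cur = ids.index(p_star)
    d = np.sqrt(((mus - mus[i_cur]) ** 2).sum(axis=1))
    if dparams.distance_norm == "diagonal":
        d = d / diag
    nu = dparams.eta * (vals / vals[i_cur]) * np.exp(-dparams.kappa * d)
    nu[i_cur] *= np.exp(-dparams.phi * vals[i_cur] * t_on_patch)
    return nu


def random_baseline(
    frame_w: float,
    frame_h: float,
    duration_s: float,
    seed: int | np.random.Generator,
    k_center: float = 1.0 / 6.0,
) -> Scanpath:
    """Center-biased random scanpath baseline.

    Fixation coordinates are i.i.d. from an isotropic Gaussian at the
    frame center with standard deviation ``k_center * frame_h``; fixation
    durations are i.i.d. uniform on [67, 1699] ms (the 1st and 99th
    percentiles of human fixation durations on conversational clips).
    Fixations are appended until their cumulative duration covers
    ``duration_s``; saccades are the implied straight connectors of zero
    duration.
    """
    if duration_s <= 0:
        raise ValueError("duration must be positive")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = k_center * frame_h
    center = np.array([frame_w / 2.0, frame_h / 2.0])
    xs, ys, onsets, durs = [], [], [], []
    t = 0.0
    while t < duration_s:
        pos = center + sd * rng.standard_normal(2)
        d = rng.uniform(0.067, 1.699)
        xs.append(min(max(pos[0], 0.0), frame_w))
        ys.append(min(max(pos[1], 0.0), frame_h))
        onsets.append(t)
        durs.append(d)
        t += d
    return Scanpath(
        x=np.array(xs), y=np.array(ys), onset=np.array(onsets),
        duration=np.array(durs),
        meta={"frame_w": frame_w, "frame_h": frame_h, "source": "random_baseline"},
    )


def run_cohort(
    landscape: Landscape,
    config: SimConfig,
    n_observers: int,
    base_seed: int,
) -> list[Trajectory]:
    """Simulate ``n_observers`` independent artificial observers.

    Observer *i* uses seed ``base_seed + i``; the cohort is reproducible
    and each member equals a standalone :func:`simulate` call with the
    same derived seed.
    """
    if n_observers < 1:
        raise ValueError("n_observers must be >= 1")
    return [simulate(landscape, config, seed=base_seed + i) for i in range(n_observers)]
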