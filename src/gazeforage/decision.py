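"""Multi-alternative race of evidence accumulators for patch choice.

One drift-diffusion racer per visible patch integrates noisy evidence
``dq_p = I_p dt + c dW``; the first racer to hit the threshold ``a``
determines both the moment of giving up the current patch and the next
patch to gaze at.  The drift ``I_p = Psi(p, p*) * nu_p`` combines

* a *gazing function* ``Psi`` that exponentially discounts the currently
  exploited patch in the time spent on it (``exp(-phi * V_p * t)``), so
  the process cannot stay glued to one patch forever, and
* a *relative value* ``nu_p = eta * (V_p / V_p*) * exp(-kappa * d)`` that
  scales each competitor by its value relative to the current patch and
  by its visibility (an exponential decay in the distance ``d`` between
  patch centers).

High-value current patches depress every competitor's drift (the ratio
``V_p / V_p*`` shrinks), producing longer residence times — the
mechanistic analogue of a forager staying longer in a rich patch.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .landscape import Patch

__all__ = [
    "DecisionParams",
    "RaceState",
    "RaceOutcome",
    "gazing_function",
    "relative_value",
    "drift_rates",
    "step_race",
    "check_threshold",
    "run_race",
]


@dataclass
class DecisionParams:
    """Race parameters.

    phi, eta, kappa and the threshold a default to the values obtained by
    grid search against human scanpaths (phi=0.18, eta=5, kappa=15,
    a=1.7); the noise scale is c=1 and the integration step dt is 1/60 s,
    the eye-tracker sampling interval.  ``distance_norm`` selects whether
    the center distance in the visibility term is divided by the frame
    diagonal ("diagonal", default — makes kappa unitless and kappa=15
    meaningful) or used raw in pixels ("pixels").
    """

    phi: float = 0.18
    eta: float = 5.0
    kappa: float = 15.0
    a: float = 1.7
    c: float = 1.0
    dt: float = 1.0 / 60.0
    distance_norm: str = "diagonal"
    max_race_s: float = 30.0

    def __post_init__(self) -> None:
        for name in ("phi", "eta", "kappa", "a", "dt"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.c < 0:
            raise ValueError("c must be >= 0")
        if self.distance_norm not in ("diagonal", "pixels"):
            raise ValueError("distance_norm must be 'diagonal' or 'pixels'")

    @classmethod
    def from_dict(cls, d: Mapping) -> "DecisionParams":
        return cls(**dict(d))


@dataclass
class RaceState:
    """Evidence vector plus bookkeeping for one race.

    ``q[i]`` is the accumulated evidence for ``patch_ids[i]``; ``p_star``
    is the currently exploited patch and ``t_on_patch`` the seconds since
    it was entered (the clock that the gazing function discounts; it
    resets only on patch switches, not between races on the same patch).
    """

    q: np.ndarray
    p_star: int
    t_on_patch: float
    patch_ids: list[int]

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        if len(self.q) != len(self.patch_ids):
            raise ValueError("q and patch_ids must have equal length")
        if self.p_star not in self.patch_ids:
            raise ValueError(f"p_star {self.p_star} not among patch_ids")

    @classmethod
    def fresh(cls, patch_ids: Sequence[int], p_star: int, t_on_patch: float = 0.0) -> "RaceState":
        """All racers reset to q=0 — the initial condition of every race."""
        return cls(
            q=np.zeros(len(patch_ids)),
            p_star=int(p_star),
            t_on_patch=float(t_on_patch),
            patch_ids=[int(i) for i in patch_ids],
        )

    def sync_patches(self, patch_ids: Sequence[int]) -> "RaceState":
        """Align the racer set with the patches visible now.

        Patches that disappeared are dropped from the race; newly appeared
        patches join with q=0.  Order follows ``patch_ids``.
        """
        ids = [int(i) for i in patch_ids]
        old = dict(zip(self.patch_ids, self.q))
        return RaceState(
            q=np.array([old.get(i, 0.0) for i in ids]),
            p_star=self.p_star,
            t_on_patch=self.t_on_patch,
            patch_ids=ids,
        )


@dataclass
class RaceOutcome:
    """Result of a completed race, with per-step evidence traces."""

    winner: int
    decision_time: float
    trace_t: np.ndarray = field(repr=False)
    trace_q: np.ndarray = field(repr=False)  # (n_steps, n_patches) at trace patch set
    trace_ids: list[int] = field(repr=False)

    def traces_to_frame(self):
        """Long-form (t, patch_id, q) table for plotting racer evolution."""
        import pandas as pd

        rows = {
            "t": np.repeat(self.trace_t, len(self.trace_ids)),
            "patch_id": np.tile(self.trace_ids, len(self.trace_t)),
            "q": self.trace_q.ravel(),
        }
        return pd.DataFrame(rows)


def gazing_function(p: int, p_star: int, t_on_patch: float, v_p: float, phi: float) -> float:
    """Exponential discount of the exploited patch: exp(-phi*V_p*t) if p==p*, else 1."""
    if t_on_patch < 0:
        raise ValueError("t_on_patch must be >= 0")
    if p != p_star:
        return 1.0
    return float(np.exp(-phi * v_p * t_on_patch))


def _patch_lookup(frame: Sequence[Patch]) -> dict[int, Patch]:
    return {p.id: p for p in frame}


def relative_value(
    p: int,
    p_star: int,
    frame: Sequence[Patch],
    eta: float,
    kappa: float,
    diag: float | None = None,
) -> float:
    """Visibility-weighted relative value nu_p = eta*(V_p/V_p*)*exp(-kappa*d).

    ``d`` is the Euclidean distance between the centers of patch ``p`` and
    the current patch ``p_star``, divided by the frame diagonal when
    ``diag`` is given (the default pipeline behavior) or raw pixels when
    ``diag`` is None.
    """
    patches = _patch_lookup(frame)
    if p not in patches or p_star not in patches:
        raise KeyError(f"patch {p if p not in patches else p_star} not in frame")
    cur = patches[p_star]
    if cur.value <= 0:
        raise ValueError(f"current patch {p_star} has nonpositive value {cur.value}")
    other = patches[p]
    d = float(np.linalg.norm(other.mu - cur.mu))
    if diag is not None:
        d /= diag
    return float(eta * (other.value / cur.value) * np.exp(-kappa * d))


def drift_rates(
    state: RaceState,
    frame: Sequence[Patch],
    params: DecisionParams,
    diag: float | None = None,
) -> np.ndarray:
    """Drift I_p = Psi(p, p*) * nu_p for each racer, aligned to state.patch_ids.

    Values and positions are re-read from ``frame`` each call, so speaker
    turns that change mid-race are reflected immediately.
    """
    patches = _patch_lookup(frame)
    missing = [i for i in state.patch_ids if i not in patches]
    if missing:
        raise KeyError(f"race patches {missing} not in frame; call sync_patches first")
    if diag is None and params.distance_norm == "diagonal":
        raise ValueError("distance_norm='diagonal' requires the frame diagonal")
    d_norm = diag if params.distance_norm == "diagonal" else None

    cur = patches[state.p_star]
    if cur.value <= 0:
        raise ValueError(f"current patch {state.p_star} has nonpositive value")
    if state.t_on_patch < 0:
        raise ValueError("t_on_patch must be >= 0")
    mus = np.array([patches[i].mu for i in state.patch_ids])
    vals = np.array([patches[i].value for i in state.patch_ids])
    d = np.linalg.norm(mus - cur.mu, axis=1)
    if d_norm is not None:
        d = d / d_norm
    nu = params.eta * (vals / cur.value) * np.exp(-params.kappa * d)
    psi = np.ones(len(state.patch_ids))
    i_cur = state.patch_ids.index(state.p_star)
    psi[i_cur] = np.exp(-params.phi * cur.value * state.t_on_patch)
    return psi * nu


def step_race(
    state: RaceState,
    drifts: np.ndarray,
    params: DecisionParams,
    rng: np.random.Generator,
) -> RaceState:
    """One Euler step of the race SDE: q += I*dt + c*sqrt(dt)*z, z ~ N(0,1).

    No reflecting floor is applied; negative excursions are allowed.
    ``t_on_patch`` advances by dt.
    """
    drifts = np.asarray(drifts, dtype=float)
    if drifts.shape != state.q.shape:
        raise ValueError("drifts must align with state.q")
    dt = params.dt
    noise = params.c * np.sqrt(dt) * rng.standard_normal(len(state.q)) if dt > 0 else 0.0
    return RaceState(
        q=state.q + drifts * dt + noise,
        p_star=state.p_star,
        t_on_patch=state.t_on_patch + dt,
        patch_ids=list(state.patch_ids),
    )


def check_threshold(state: RaceState, a: float) -> int | None:
    """Return the winning patch id, or None while every racer is below a.

    If several racers are at or above threshold after the same step, the
    one with the largest q wins; exact ties go to the lowest patch id.
    """
    above = state.q >= a
    if not above.any():
        return None
    qmax = state.q[above].max()
    winners = [pid for pid, q, hit in zip(state.patch_ids, state.q, above) if hit and q == qmax]
    return min(winners)


def run_race(
    state0: RaceState,
    landscape,
    params: DecisionParams,
    rng: np.random.Generator,
    t0: float = 0.0,
    record_traces: bool = True,
) -> RaceOutcome:
    """Iterate drift -> step -> threshold until a racer wins.

    The landscape frame is re-read at ``t0 + elapsed`` every step, so both
    patch membership and patch values track the scene.  Raises
    ``TimeoutError`` if no decision is reached within ``params.max_race_s``
    of race time — a symptom of degenerate parameters.
    """
    if np.any(state0.q != 0.0):
        raise ValueError("races start with all q = 0")
    state = state0
    diag = landscape.diag
    elapsed = 0.0
    ts = [0.0]
    qs = [state.q.copy()] if record_traces else None
    trace_ids = list(state.patch_ids)
    while True:
        frame = landscape.frame_at(min(t0 + elapsed, landscape.duration - 1e-9))
        ids = [p.id for p in frame]
        if ids != state.patch_ids:
            state = state.sync_patches(ids)
        drifts = drift_rates(state, frame, params, diag)
        state = step_race(state, drifts, params, rng)
        elapsed += params.dt
        if record_traces:
            ts.append(elapsed)
            if state.patch_ids != trace_ids:
                # patch set changed mid-race: restart traces at the new set
                trace_ids = list(state.patch_ids)
                ts = [elapsed]
                qs = []
            qs.append(state.q.copy())
        winner = check_threshold(state, params.a)
        if winner is not None:
            return RaceOutcome(
                winner=winner,
                decision_time=elapsed,
                trace_t=np.asarray(ts) if record_traces else np.empty(0),
                trace_q=np.asarray(qs) if record_traces else np.empty((0, 0)),
                trace_ids=trace_ids,
            )
        if elapsed >= params.max_race_s:
            raise TimeoutError(
                f"race exceeded {params.max_race_s} s without a decision; "
                "check threshold/drift parameters"
            )
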