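"""Two-scale Ornstein-Uhlenbeck spatial dynamics of gaze.

Gaze position r_F(t) follows a 2-D mean-reverting diffusion
``dr = B (mu - r) dt + sigma dW`` whose attractor mu is the center of the
currently selected patch.  The same process operates at two scales,
switched by the regime flag s_t:

* s_t = 0 (exploitation): attraction strength b is set per axis from the
  patch width (narrow patches pull harder), diffusion sigma = 1 — small
  wander inside the patch.
* s_t = 1 (relocation): b is set from the remaining distance to the
  target and sigma from the mean pairwise distance between patch centers
  — a large, fast sweep across the landscape.

Steps use the exact O-U transition: per axis

    x' = x e^{-b dt} + mu (1 - e^{-b dt}) + (sigma/sqrt(2b)) sqrt(1 - e^{-2b dt}) z

with z ~ N(0,1), which is distributionally exact for any dt.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np

from .landscape import Patch

__all__ = [
    "SpatialConfig",
    "OUParams",
    "GazeState",
    "ou_params_for",
    "ou_step",
    "has_arrived",
    "mean_pairwise_distance",
]


@dataclass
class SpatialConfig:
    """Proportionality constants and switches of the spatial process.

    k_b_local divides the patch width (px) to give the local attraction
    b (1/s): a 20 px-wide patch with k_b_local=40 relaxes at b=2/s.
    k_b_global divides the remaining distance (px) during relocation
    (``relocate_drift='inverse'``, default): drift stiffens as the target
    nears, so relocations terminate; 'direct' scales b with the
    diagonal-normalized distance instead.  b is always clamped to
    [b_min, b_max].  k_sigma_global scales the mean pairwise patch-center
    distance into the relocation diffusion.  ``ou_noise`` selects the
    exact conditional standard deviation ('exact', default) or the
    literal factor sigma*b*(1 - e^{-2b dt}) ('literal') for comparison.
    """

    k_b_local: float = 40.0
    k_b_global: float = 20.0
    k_sigma_global: float = 0.25
    b_min: float = 0.5
    b_max: float = 50.0
    ou_noise: str = "exact"
    relocate_drift: str = "inverse"
    arrival_mahalanobis: float = 1.0

    def __post_init__(self) -> None:
        if self.ou_noise not in ("exact", "literal"):
            raise ValueError("ou_noise must be 'exact' or 'literal'")
        if self.relocate_drift not in ("inverse", "direct"):
            raise ValueError("relocate_drift must be 'inverse' or 'direct'")
        if self.b_min <= 0 or self.b_max < self.b_min:
            raise ValueError("need 0 < b_min <= b_max")

    @classmethod
    def from_dict(cls, d: Mapping) -> "SpatialConfig":
        return cls(**dict(d))


@dataclass
class OUParams:
    """Per-axis attraction b (1/s), diffusion scale sigma, and regime flag."""

    b: np.ndarray  # shape (2,), strictly positive
    sigma: float
    regime: int  # 0 = exploit, 1 = relocate
    noise: str = "exact"

    def __post_init__(self) -> None:
        self.b = np.asarray(self.b, dtype=float).reshape(2)
        if np.any(self.b <= 0):
            raise ValueError("b must be strictly positive per axis")
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.regime not in (0, 1):
            raise ValueError("regime must be 0 or 1")

    @property
    def gamma(self) -> np.ndarray:
        """Stationary standard deviation sigma/sqrt(2b) per axis."""
        return self.sigma / np.sqrt(2.0 * self.b)


@dataclass
class GazeState:
    """Instantaneous gaze state: position, regime, attractor, clock."""

    r: np.ndarray  # (x, y) px, unclamped internal state
    regime: int
    attractor: int
    t: float

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=float).reshape(2)
        if not np.all(np.isfinite(self.r)):
            raise ValueError("gaze position must be finite")


def mean_pairwise_distance(frame: Sequence[Patch]) -> float:
    """Mean Euclidean distance between all unordered pairs of patch centers.

    Zero for a single-patch frame (no pairs).
    """
    mus = [p.mu for p in frame]
    if len(mus) < 2:
        return 0.0
    return float(np.mean([np.linalg.norm(a - b) for a, b in combinations(mus, 2)]))


def ou_params_for(
    state: GazeState,
    patch: Patch,
    frame: Sequence[Patch],
    config: SpatialConfig,
    diag: float | None = None,
) -> OUParams:
    """Regime-dependent O-U parameters for the current attractor patch.

    During relocation the remaining distance to the target is expressed in
    frame diagonals when ``diag`` is given (the pipeline default), which
    keeps the attraction strength — and hence saccade speed — independent
    of the pixel resolution; with ``diag=None`` the raw pixel distance is
    used.
    """
    if state.regime == 0:
        width = patch.width
        if np.any(width <= 0):
            raise ValueError(f"patch {patch.id} has zero width")
        b = config.k_b_local / width
        sigma = 1.0
    else:
        d = float(np.linalg.norm(state.r - patch.mu))
        if diag is not None:
            d /= diag
        if config.relocate_drift == "inverse":
            b_scalar = config.k_b_global / max(d, 1e-12)
        else:
            b_scalar = config.k_b_global * d
        b = np.full(2, np.clip(b_scalar, config.b_min, config.b_max))
        sigma = config.k_sigma_global * mean_pairwise_distance(frame)
    return OUParams(b=b, sigma=sigma, regime=state.regime, noise=config.ou_noise)


def ou_step(
    r: np.ndarray,
    mu: np.ndarray,
    params: OUParams,
    dt: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Advance gaze by one exact O-U transition of length dt.

    Broadcasts over leading dimensions of ``r`` (shape (..., 2)), drawing
    independent standard-normal noise per axis and per trailing point.
    With ``params.noise == 'literal'`` the noise amplitude is the raw
    factor sigma*b*(1 - e^{-2b dt}) instead of the exact conditional
    standard deviation.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    r = np.asarray(r, dtype=float)
    mu = np.asarray(mu, dtype=float)
    b = params.b
    decay = np.exp(-b * dt)
    mean = r * decay + mu * (1.0 - decay)
    if params.noise == "exact":
        sd = (params.sigma / np.sqrt(2.0 * b)) * np.sqrt(1.0 - np.exp(-2.0 * b * dt))
    else:
        sd = params.sigma * b * (1.0 - np.exp(-2.0 * b * dt))
    z = rng.standard_normal(r.shape)
    return mean + sd * z


def has_arrived(r: np.ndarray, patch: Patch, threshold: float = 1.0) -> bool:
    """True once gaze is within ``threshold`` Mahalanobis units of the patch.

    The arrival criterion that terminates a relocation: the point lies on
    or inside the threshold-sigma ellipse of the target Gaussian.
    """
    r = np.asarray(r, dtype=float).reshape(2)
    delta = r - patch.mu
    try:
        m2 = float(delta @ np.linalg.solve(patch.sigma, delta))
    except np.linalg.LinAlgError as exc:
        raise ValueError(f"patch {patch.id} covariance is singular") from exc
    # inclusive boundary, robust to round-off in the quadratic form
    return m2 <= threshold**2 * (1.0 + 1e-9)
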