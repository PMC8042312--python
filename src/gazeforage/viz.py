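"""Basic plotting helpers: racer traces, gaze trajectories, score densities.

All functions take/return matplotlib axes so they compose with user
figures; nothing here is required by the computational pipeline.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_racer_traces", "plot_trajectory", "plot_score_densities"]


def plot_racer_traces(outcome, threshold: float, ax=None):
    """Evidence accumulation traces of one race, with the decision bound."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for j, pid in enumerate(outcome.trace_ids):
        ax.plot(outcome.trace_t, outcome.trace_q[:, j], label=f"patch {pid}")
    ax.axhline(threshold, color="k", ls="--", lw=1, label="threshold a")
    ax.set_xlabel("race time (s)")
    ax.set_ylabel("evidence q(t)")
    ax.legend(fontsize="small")
    return ax


def plot_trajectory(trajectory, landscape=None, ax=None):
    """Gaze path colored by regime (exploitation vs relocation)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    x, y, s = trajectory.x, trajectory.y, trajectory.regime
    ax.plot(x[s == 0], y[s == 0], ".", ms=2, color="tab:blue", label="exploit")
    ax.plot(x[s == 1], y[s == 1], ".", ms=2, color="tab:red", label="relocate")
    if landscape is not None:
        for p in landscape.frames[0]:
            w = np.sqrt(np.diag(p.sigma))
            ax.add_patch(
                __import__("matplotlib.patches", fromlist=["Ellipse"]).Ellipse(
                    p.mu, 2 * w[0], 2 * w[1], fill=False, color="gray", lw=1
                )
            )
        ax.set_xlim(0, landscape.frame_w)
        ax.set_ylim(landscape.frame_h, 0)
    ax.set_xlabel("x (px)")
    ax.set_ylabel("y (px)")
    ax.legend(fontsize="small")
    return ax


def plot_score_densities(densities: dict, score: str, ax=None):
    """Overlay per-model kernel density estimates of one similarity score."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for (group, col), d in densities.items():
        if col != score:
            continue
        ax.plot(d["grid"], d["density"], label=str(group))
    ax.set_xlabel(score)
    ax.set_ylabel("density")
    ax.legend(fontsize="small")
    return ax
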