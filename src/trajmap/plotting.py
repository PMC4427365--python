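"""Minimal plotting convenience: state-indicator curves along a trajectory."""

from __future__ import annotations

import numpy as np

__all__ = ["plot_indicator_curves"]


def plot_indicator_curves(times, curves, state_ids, path=None, ax=None):
    """Plot f_α(t) for every state; near-1 plateaus mark occupied states."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    curves = np.atleast_2d(curves)
    if ax is None:
        _, ax = plt.subplots(figsize=(8, 3))
    for k, sid in enumerate(state_ids):
        ax.plot(times, curves[:, k], lw=0.8, label=f"S{sid}")
    ax.set_xlabel("time (ps)")
    ax.set_ylabel(r"$f_\alpha(t)$")
    ax.set_ylim(-0.1, 1.1)
    if len(state_ids) <= 10:
        ax.legend(fontsize=7, ncol=min(len(state_ids), 5))
    if path is not None:
        ax.figure.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(ax.figure)
    return ax
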