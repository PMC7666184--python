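"""Correlogram-style plot of a removal cascade."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .cascade import CascadeTrace

__all__ = ["plot_cascade"]

_STYLE = [
    ("frac_a", "environment", "black", "o"),
    ("frac_c", "space", "white", "o"),
    ("frac_b", "shared", "grey", "o"),
    ("frac_d", "residual", "red", "o"),
]


def plot_cascade(trace: CascadeTrace, path: str | Path | None = None, ax=None):
    """Fractions of the partition against the number of species removed.

    Filled black = pure environment, open = pure space, grey = shared,
    red = residual.
    """
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    steps = [s for s, _, _ in trace.steps]
    for comp, label, color, marker in _STYLE:
        ax.plot(
            steps,
            trace.component_path(comp),
            marker=marker,
            linestyle="-",
            markerfacecolor=color,
            markeredgecolor="black",
            color="lightgrey",
            label=label,
        )
    ax.set_xlabel("species removed")
    ax.set_ylabel("adjusted fraction")
    ax.set_title(trace.direction.replace("_", " "))
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return ax
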