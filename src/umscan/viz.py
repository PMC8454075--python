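"""Static U/M-plane scatter plots."""

from __future__ import annotations

from pathlib import Path

import numpy as np


def plot_um(
    points: np.ndarray,
    assignments: np.ndarray | None = None,
    title: str = "",
    path: str | Path | None = None,
):
    """Scatter U against M, optionally colored by cluster assignment.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    points = np.asarray(points, dtype=float)
    fig, ax = plt.subplots(figsize=(5, 5))
    c = assignments if assignments is not None else "tab:blue"
    ax.scatter(points[:, 0], points[:, 1], c=c, s=8, cmap="viridis", alpha=0.7)
    ax.set_xlabel("U (unmethylated intensity)")
    ax.set_ylabel("M (methylated intensity)")
    ax.set_title(title)
    ax.set_aspect("equal", adjustable="datalim")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
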