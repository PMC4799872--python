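"""Per-sample log2 copy-ratio profile plots.

One panel per sample: log2 ratio against genome order, fixed threshold
guide lines, called spans shaded, gene boundaries ticked.  Figure size
and dpi are fixed so identical inputs give identical plots.
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .core import CnvCall, Log2RatioMatrix, Thresholds

_FIGSIZE = (12.0, 3.5)
_DPI = 100


def plot_sample_profile(
    sample_id: str,
    l2m: Log2RatioMatrix,
    calls: Sequence[CnvCall],
    path: str | Path,
    thresholds: Thresholds | None = None,
) -> dict:
    """Render one sample's profile to ``path``.

    Returns plot metadata (point count and highlighted spans) so tests
    and callers can verify content without parsing the image.
    """
    thresholds = thresholds or Thresholds()
    i = l2m.sample_index(sample_id)  # KeyError for unknown samples
    row = l2m.log2ratio[i]
    masked = l2m.mask[i]
    ok = ~masked & np.isfinite(row)
    x = np.flatnonzero(ok)
    y = row[ok]

    sample_calls = [c for c in calls if c.sample_id == sample_id]

    fig, ax = plt.subplots(figsize=_FIGSIZE, dpi=_DPI)
    ax.scatter(x, y, s=8, c="0.35", zorder=3)
    ax.axhline(0.0, color="0.8", lw=0.8, zorder=1)
    ax.axhline(
        thresholds.gain_min_log2, color="tab:red", ls="--", lw=0.8, zorder=2
    )
    ax.axhline(
        thresholds.loss_max_log2, color="tab:blue", ls="--", lw=0.8, zorder=2
    )
    highlights = []
    for c in sample_calls:
        color = "tab:red" if c.direction == "gain" else "tab:blue"
        ax.axvspan(
            c.first_target - 0.5, c.last_target + 0.5, color=color, alpha=0.2
        )
        highlights.append((c.first_target, c.last_target, c.direction))

    genes = l2m.targets.genes
    boundaries = [0] + [
        j for j in range(1, len(genes)) if genes[j] != genes[j - 1]
    ]
    for b in boundaries:
        ax.axvline(b - 0.5, color="0.9", lw=0.4, zorder=0)

    ax.set_xlabel("relative genome order")
    ax.set_ylabel("log2 ratio")
    ax.set_title(sample_id)
    ax.set_xlim(-1, len(genes))
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
    return {
        "path": str(path),
        "n_points": int(ok.sum()),
        "highlights": highlights,
    }
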