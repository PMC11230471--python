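"""Minimal plotting helpers (untested decoration).

Quick-look figures for peri-event matrices: per-trial heatmap above the
trial-mean trace, the layout used for locomotion-aligned population
activity.
"""

from __future__ import annotations

import numpy as np


def perievent_heatmap(matrix, ax=None, cmap: str = "viridis"):
    """Heatmap of trials x relative time with the event marked at 0."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = [matrix.rel_time[0], matrix.rel_time[-1],
              matrix.values.shape[0], 0]
    im = ax.imshow(matrix.values, aspect="auto", extent=extent, cmap=cmap)
    ax.axvline(0.0, color="w", lw=0.8, ls="--")
    ax.set_xlabel(f"time from {matrix.event_kind} (s)")
    ax.set_ylabel("trial")
    return im


def perievent_mean(matrix, ax=None, color="k"):
    """Trial-mean trace with a SEM band."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    m = matrix.mean_trace()
    sem = matrix.values.std(axis=0, ddof=1) / np.sqrt(matrix.values.shape[0]) \
        if matrix.values.shape[0] > 1 else np.zeros_like(m)
    ax.plot(matrix.rel_time, m, color=color)
    ax.fill_between(matrix.rel_time, m - sem, m + sem, alpha=0.3, color=color)
    ax.axvline(0.0, color="gray", lw=0.8, ls="--")
    ax.set_xlabel(f"time from {matrix.event_kind} (s)")
    return ax
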