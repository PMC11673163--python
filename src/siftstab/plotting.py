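"""Minimal plotting helpers for stability and sweep outputs."""

from __future__ import annotations

import numpy as np


def plot_stability_scatter(records, ax_pair=None):
    """Stability rate vs contrast (left) and vs eigenvalue ratio (right)."""
    import matplotlib.pyplot as plt

    if ax_pair is None:
        _, ax_pair = plt.subplots(1, 2, figsize=(9, 4))
    stab = [r.stability_rate for r in records]
    ax_pair[0].scatter([r.contrast for r in records], stab, s=8, alpha=0.5)
    ax_pair[0].set_xlabel("keypoint contrast |D(x̂)|")
    ax_pair[0].set_ylabel("stability rate")
    ax_pair[1].scatter([r.evr for r in records], stab, s=8, alpha=0.5)
    ax_pair[1].set_xlabel("eigenvalue ratio")
    ax_pair[1].set_ylabel("stability rate")
    return ax_pair


def plot_sweep(results, axis: str, metric: str = "median_rmse", ax=None):
    """Median trend of one sweep axis ('contrast' or 'evr')."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    pts = sorted((r for r in results if r.axis == axis),
                 key=lambda r: getattr(r, f"{axis}_thresh"))
    x = [getattr(r, f"{axis}_thresh") for r in pts]
    y = [getattr(r, metric) for r in pts]
    ax.plot(x, y, marker="o")
    ax.set_xlabel(f"{axis} threshold")
    ax.set_ylabel(metric.replace("_", " "))
    return ax
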