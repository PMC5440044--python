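"""Matplotlib helpers for profiles, timing distributions and overlays.

Optional: importing this module requires matplotlib (``pip install
replitime[plot]``); nothing else in the package depends on it.
"""

from __future__ import annotations

import numpy as np

from replitime.enrichment import EnrichmentTrack
from replitime.timing import ReplicationTimingResults


def plot_profile(track: EnrichmentTrack, chrom: str, ax=None, **kwargs):
    """Plot one chromosome of a per-bin track against position (kb)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 2.5))
    sl = track.genome.chrom_slice(chrom)
    x = (np.arange(sl.stop - sl.start) * track.genome.bin_width
         + track.genome.bin_width // 2) / 1000.0
    ax.plot(x, track.values[sl], lw=0.8, **kwargs)
    ax.set_xlabel(f"{chrom} position (kb)")
    ax.set_ylabel(track.stage or "signal")
    return ax


def plot_extent_distributions(
    results_by_condition: dict[str, ReplicationTimingResults],
    bins_by_class: dict[str, np.ndarray],
    g_values=(0.25, 0.5, 0.75),
    axes=None,
):
    """Box plots of F(G, x) per region class and condition, one panel per G."""
    import matplotlib.pyplot as plt

    g_values = list(g_values)
    if axes is None:
        _, axes = plt.subplots(1, len(g_values), figsize=(4 * len(g_values), 3),
                               sharey=True)
    for ax, g in zip(np.atleast_1d(axes), g_values):
        data, labels = [], []
        for cls, idx in bins_by_class.items():
            for cond, res in results_by_condition.items():
                f = res.evaluate_extent([g])[0][idx]
                data.append(f[~np.isnan(f)])
                labels.append(f"{cls}\n{cond}")
        ax.boxplot(data, tick_labels=labels)
        ax.set_title(f"G = {g:g}")
        ax.set_ylabel("local extent F(G, x)")
    return axes


def plot_overlay(overlay: dict, ax=None, label: str = "", **kwargs):
    """Plot a peak-normalised ensemble overlay average against offset (kb)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 3))
    ax.plot(overlay["offsets_bp"] / 1000.0, overlay["average"], label=label, **kwargs)
    ax.set_xlabel("distance from origin peak (kb)")
    ax.set_ylabel("normalised enrichment")
    if label:
        ax.legend()
    return ax
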