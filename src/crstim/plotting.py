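"""Small plotting helpers: metric boxplots, resetting-index curves, matrices."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def boxplot_by_protocol(summary, metric, ax=None, order=None):
    """Boxplots of one per-sample metric grouped by protocol."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    protocols = order or list(dict.fromkeys(summary["protocol"]))
    data = [summary.loc[summary["protocol"] == p, metric].to_numpy() for p in protocols]
    ax.boxplot(data, tick_labels=protocols)
    ax.set_ylabel(metric)
    ax.tick_params(axis="x", rotation=45)
    return ax


def plot_resetting_index(lags_ms, curves: dict, ax=None):
    """Resetting-index E(dt) curves, one per protocol."""
    if ax is None:
        _, ax = plt.subplots(figsize=(7, 4))
    for label, E in curves.items():
        ax.plot(lags_ms, E, label=label)
    ax.axvline(0.0, color="k", lw=0.5)
    ax.set_xlabel(r"$\Delta t$ (ms)")
    ax.set_ylabel(r"$E(\Delta t)$")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=8)
    return ax


def plot_connectivity(matrix, ax=None, vmax=1.0):
    """Signed connectivity (or sorted-connectivity) matrix as an image."""
    if ax is None:
        _, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(
        matrix, cmap="RdBu_r", vmin=-vmax, vmax=vmax, origin="upper",
        extent=(0.5, matrix.shape[1] + 0.5, matrix.shape[0] + 0.5, 0.5),
    )
    plt.colorbar(im, ax=ax, shrink=0.8)
    ax.set_xlabel("neuron j")
    ax.set_ylabel("neuron i")
    return ax
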