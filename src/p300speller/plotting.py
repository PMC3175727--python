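"""Optional matplotlib views of the evaluation products."""

from __future__ import annotations

import numpy as np

from .evaluation import AccuracyCurve, DispersionCurve, ErrorGrid, MAX_OFFSET


def plot_accuracy_curves(curves: list[AccuracyCurve], ax=None):
    """Accuracy vs. number of intensification sequences, one line per method."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    for c in curves:
        ax.plot(c.ks, 100 * np.asarray(c.accuracies), marker="o", label=c.method)
    ax.set_xlabel("intensification sequences k")
    ax.set_ylabel("character accuracy [%]")
    ax.set_ylim(0, 102)
    ax.legend()
    return ax


def plot_error_grid(grid: ErrorGrid, ax=None, title: str = ""):
    """Heatmap of typed-minus-intended (row, column) offsets, in percent."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    extent = (-MAX_OFFSET - 0.5, MAX_OFFSET + 0.5) * 2
    im = ax.imshow(grid.values, origin="lower", extent=extent, cmap="viridis")
    ax.set_xlabel("column offset")
    ax.set_ylabel("row offset")
    if title:
        ax.set_title(title)
    plt.colorbar(im, ax=ax, label="% of typed characters")
    return ax


def plot_dispersion(curves: list[DispersionCurve], ax=None):
    """Directional offset standard deviations vs. k."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, axes = plt.subplots(1, 2, sharey=True)
    else:
        axes = ax
    for c in curves:
        axes[0].plot(c.ks, c.vertical_std, marker="o", label=c.method)
        axes[1].plot(c.ks, c.horizontal_std, marker="o", label=c.method)
    axes[0].set_title("vertical (rows)")
    axes[1].set_title("horizontal (columns)")
    for a in axes:
        a.set_xlabel("intensification sequences k")
    axes[0].set_ylabel("offset std")
    axes[0].legend()
    return axes


def plot_windowed_accuracy(acc_by_center: dict[float, float], ax=None):
    """Accuracy of 50 ms feature windows against their centre latency."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    centers = sorted(acc_by_center)
    ax.plot(centers, [100 * acc_by_center[c] for c in centers], marker="o")
    ax.set_xlabel("window centre [ms after onset]")
    ax.set_ylabel("character accuracy [%]")
    return ax
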