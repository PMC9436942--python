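"""Optional matplotlib rendering of metric panels and disparity tables.

Matplotlib is an optional dependency (install extra ``plot``); everything
here degrades to a clear ImportError if it is missing. All figures can
also be reproduced from the CSV outputs of the CLI.
"""

from __future__ import annotations

import pandas as pd

from .metrics import METRIC_COLUMNS


def _plt():
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "plotting requires matplotlib (pip install dpfair[plot])"
        ) from exc
    return plt


def plot_subgroup_heatmap(frame: pd.DataFrame, path: str) -> None:
    """Render a subgroup-by-metric panel (rows = subgroups) to PNG."""
    plt = _plt()
    cols = [c for c in METRIC_COLUMNS if c in frame.columns]
    mat = frame.set_index("subgroup")[cols].astype(float)
    fig, ax = plt.subplots(figsize=(1.2 * len(cols), 0.5 * len(mat) + 1.5))
    im = ax.imshow(mat.to_numpy(), vmin=0, vmax=1, cmap="viridis", aspect="auto")
    ax.set_xticks(range(len(cols)), cols, rotation=45, ha="right")
    ax.set_yticks(range(len(mat)), mat.index)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_disparity_comparison(table: pd.DataFrame, path: str) -> None:
    """Bar chart of relative disparity per correction method, one panel
    per (attribute, metric) column; the 1.25 fair line is drawn."""
    plt = _plt()
    cols = [c for c in table.columns if c != "method"]
    fig, axes = plt.subplots(1, len(cols), figsize=(3.2 * len(cols), 3.5),
                             squeeze=False)
    for ax, col in zip(axes[0], cols):
        ax.bar(table["method"], table[col])
        ax.axhline(1.25, color="red", linestyle="--", linewidth=1)
        ax.set_title(col, fontsize=9)
        ax.tick_params(axis="x", rotation=75, labelsize=7)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
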