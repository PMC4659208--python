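"""Line-chart helpers for sweep results (total and communicating flows)."""
from __future__ import annotations

from pathlib import Path

import matplotlib
matplotlib.use("Agg")
import matplotlib.pyplot as plt

from .experiments import SweepResult

__all__ = ["plot_total_flows", "plot_communicating_flows"]


def plot_total_flows(sweep: SweepResult, path: str | Path | None = None):
    """Total cerebral flow vs stenosis degree, one line per configuration."""
    table = sweep.total_flow_table()
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in table.columns:
        ax.plot(table.index, table[col], marker="o", label=col)
    ax.set_xlabel("RICA stenosis degree (%)")
    ax.set_ylabel("total flow (ml/s)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig


def plot_communicating_flows(sweep: SweepResult, segment: str,
                             path: str | Path | None = None):
    """Signed flow of one communicating artery vs stenosis degree.

    Positive is toward the right hemisphere (ACoA) or toward the
    anterior circulation (PCoAs); configurations lacking the segment are
    omitted.
    """
    table = sweep.communicating_table(segment)
    fig, ax = plt.subplots(figsize=(6, 4))
    for col in table.columns:
        if table[col].isna().all():
            continue
        ax.plot(table.index, table[col], marker="o", label=col)
    ax.axhline(0.0, color="k", lw=0.5)
    ax.set_xlabel("RICA stenosis degree (%)")
    ax.set_ylabel(f"{segment} flow (ml/s, signed)")
    ax.legend(fontsize=7)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path)
        plt.close(fig)
    return fig
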