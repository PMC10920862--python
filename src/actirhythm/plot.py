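"""Presentation graphics: double-plotted actograms and profile plots."""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .records import ActigraphyRecord
from .response import DailyProfile

__all__ = ["actogram", "plot_daily_profile"]


def actogram(record: ActigraphyRecord, path: str | Path | None = None, display_origin_zt: float = 0.0):
    """Double-plotted actogram: 48 h per line, one line per day.

    ``display_origin_zt`` shifts the horizontal axis (some labs plot from
    mid-dark rather than lights-on); data conventions are unaffected.
    """
    bpd = record.bins_per_day
    days = record.n_bins // bpd
    act = np.asarray(record.activity[: days * bpd], dtype=float).reshape(days, bpd)
    shift = int(round(display_origin_zt * 3600 / record.bin_seconds)) % bpd
    if shift:
        flat = act.reshape(-1)
        flat = np.roll(flat, -shift)
        act = flat.reshape(days, bpd)
    top = act.max() or 1.0

    fig, axes = plt.subplots(days, 1, figsize=(8, 0.35 * days + 1), sharex=True)
    if days == 1:
        axes = [axes]
    x = np.arange(2 * bpd) * record.bin_seconds / 3600.0
    for d, ax in enumerate(axes):
        left = act[d]
        right = act[d + 1] if d + 1 < days else np.zeros(bpd)
        ax.fill_between(x, 0, np.concatenate([left, right]), step="post", color="k")
        ax.set_ylim(0, top)
        ax.set_yticks([])
        ax.set_ylabel(str(d), rotation=0, fontsize=6, va="center")
    axes[-1].set_xlabel("time (h, double-plotted)")
    axes[0].set_title(f"{record.animal_id} ({record.group})")
    fig.tight_layout(h_pad=0.0)
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig


def plot_daily_profile(profiles: Sequence[DailyProfile], path: str | Path | None = None):
    """Mean +/- SEM daily profiles, one line per group."""
    fig, ax = plt.subplots(figsize=(7, 3.5))
    for p in profiles:
        ax.plot(p.bin_start_zt, p.mean, label=f"{p.group} (n={p.n_animals})")
        ax.fill_between(p.bin_start_zt, p.mean - p.sem, p.mean + p.sem, alpha=0.3)
    ax.set_xlabel("ZT (h)")
    ax.set_ylabel(profiles[0].variable)
    ax.set_xlim(0, 24)
    ax.axvspan(12, 24, color="0.85", zorder=0)
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
        return None
    return fig
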