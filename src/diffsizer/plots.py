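"""Diagnostic plots: preprocessing stages, variance-time lines, GoF scans."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .mixturefit import mixture_value


def plot_profiles(result, path: str | Path) -> Path:
    """Centered fluorescent profiles with their fitted mixtures overlaid."""
    fig, ax = plt.subplots(figsize=(7, 4.5))
    cmap = plt.get_cmap("viridis")
    n = len(result.sections)
    for i, (sp, fit) in enumerate(zip(result.sections, result.fits)):
        color = cmap(i / max(n - 1, 1))
        ax.plot(sp.x_inside, sp.fluor_inside, color=color, alpha=0.5, lw=0.8)
        xs = np.linspace(sp.x_inside[0], sp.x_inside[-1], 400)
        ax.plot(xs, mixture_value(fit.components, xs), color=color, lw=1.2)
    ax.set_xlabel("cross-channel position (um)")
    ax.set_ylabel("signal intensity")
    ax.set_title("centered profiles and fitted Gaussian mixtures")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_variance_time(result, path: str | Path) -> Path:
    """Component variances (c^2) against transit time with the fitted lines."""
    fig, ax = plt.subplots(figsize=(6, 4))
    for track, res in zip(result.tracks, result.report.results):
        ax.plot(track.times, track.variances, "o", label=f"rank {track.rank}")
        ts = np.array([track.times[0], track.times[-1]])
        ax.plot(ts, res.intercept + res.slope * ts, "-", lw=1)
    ax.set_xlabel("transit time (s)")
    ax.set_ylabel(r"variance $c^2$ (um$^2$)")
    ax.legend()
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)


def plot_order_scan(table: pd.DataFrame, path: str | Path) -> Path:
    """Four GoF metrics against mixture order, one line per measurement point."""
    fig, axes = plt.subplots(2, 2, figsize=(8, 6), sharex=True)
    for ax, metric in zip(axes.ravel(), ("sse", "rmse", "r2", "adj_r2")):
        for label, grp in table.groupby("point"):
            ax.plot(grp["order"], grp[metric], "o-", ms=3, lw=0.8, label=str(label))
        ax.set_title(metric)
        ax.set_xlabel("mixture order")
    axes[0, 0].legend(fontsize=6, ncol=2)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
    return Path(path)
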