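"""Minimal static figures for the landscape analyses."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def plot_landscape(windows, column: str = "rate_cM_Mb", path=None):
    """Per-chromosome windowed track, one panel per chromosome."""
    chroms = windows["chrom"].unique()
    fig, axes = plt.subplots(len(chroms), 1, sharey=True,
                             figsize=(8, 1.2 * len(chroms)), squeeze=False)
    for ax, chrom in zip(axes.ravel(), chroms):
        sub = windows[windows["chrom"] == chrom]
        mid = (sub["start"] + sub["end"]) / 2e6
        ax.plot(mid, sub[column], lw=0.8)
        ax.set_ylabel(chrom, rotation=0, ha="right", fontsize=8)
    axes.ravel()[-1].set_xlabel("position (Mb)")
    fig.suptitle(column)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_profile(profile, path=None, label: str = "anchors"):
    """Distance profile with its 95% band."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    x = profile.centers / 1e3
    ax.plot(x, profile.mean_rate, color="tab:blue")
    ok = np.isfinite(profile.mean_rate)
    ax.fill_between(x[ok],
                    (profile.mean_rate - profile.ci_half_width)[ok],
                    (profile.mean_rate + profile.ci_half_width)[ok],
                    alpha=0.3, color="tab:blue")
    ax.axvline(0, color="k", lw=0.8, ls="--")
    ax.set_xlabel(f"distance from {label} (kb)")
    ax.set_ylabel("mean rate (cM/Mb)")
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
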