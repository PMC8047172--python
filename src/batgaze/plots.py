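"""Report figures: binned beam vectors, day regressions, SSG bars, fingerprints."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .localize import BinnedBeam, RegressionComparison, SEGMENTS_CM

__all__ = ["plot_binned_beam", "plot_day_regressions", "plot_ssg_proportions",
           "plot_fingerprint"]


def plot_binned_beam(binned: BinnedBeam, title: str = "", path: str | Path | None = None):
    """Mean beam-aim vectors (with SD envelope) in 10-cm bins along the path."""
    fig, ax = plt.subplots(figsize=(4, 6))
    for lo, c, m, s in zip(binned.bin_lower_cm, binned.bin_centers_cm,
                           binned.mean_deg, binned.sd_deg):
        if np.isnan(m):
            continue
        dx = np.sin(np.radians(m))
        dy = np.cos(np.radians(m))
        color = "tab:blue" if m > 0 else "tab:red"
        ax.arrow(0, c, 8 * dx, 8 * dy, head_width=1.5, color=color, alpha=0.9)
        ax.fill_betweenx([c - 4, c + 4], m - s, m + s, alpha=0.0)
    ax2 = ax.twiny()
    ok = ~np.isnan(binned.mean_deg)
    ax2.plot(binned.mean_deg[ok], binned.bin_centers_cm[ok], ".-", color="0.4", lw=0.8)
    ax2.fill_betweenx(binned.bin_centers_cm[ok],
                      (binned.mean_deg - binned.sd_deg)[ok],
                      (binned.mean_deg + binned.sd_deg)[ok],
                      alpha=0.2, color="0.5")
    ax2.set_xlabel("mean beam aim (deg, + = right)")
    ax.set_ylabel("distance to turn (cm)")
    ax.set_xlim(-30, 30)
    ax.set_ylim(0, 300)
    ax.invert_yaxis()
    ax.set_xticks([])
    ax.set_title(title)
    if path:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_day_regressions(calls_first: pd.DataFrame, calls_last: pd.DataFrame,
                         comparison: RegressionComparison, title: str = "",
                         path: str | Path | None = None):
    """First- vs last-day beam angles over 150-0 cm with regression lines."""
    fig, ax = plt.subplots(figsize=(5, 4))
    lo, hi = SEGMENTS_CM["BEAM2"]
    for df, color, marker, label, slope, icpt in (
        (calls_first, "k", "o", "first day", comparison.slope_first, comparison.intercept_first),
        (calls_last, "r", "+", "last day", comparison.slope_last, comparison.intercept_last),
    ):
        d = df["distance_to_turn_cm"].to_numpy(float)
        sel = (d >= lo) & (d < hi)
        ax.plot(d[sel], df["beam_aim_deg"].to_numpy(float)[sel], marker,
                mfc="none", color=color, ms=4, alpha=0.6, label=label)
        xs = np.linspace(lo, hi, 20)
        ax.plot(xs, icpt + slope * xs, color=color, lw=1.5)
    star = " *" if comparison.significant else ""
    ax.set_xlabel("distance to turn (cm)")
    ax.set_ylabel("beam angle (deg)")
    ax.invert_xaxis()
    ax.legend(frameon=False)
    ax.set_title(f"{title}{star} (F={comparison.f_stat:.1f}, p={comparison.p_value:.2g})")
    if path:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_ssg_proportions(props: pd.DataFrame, title: str = "",
                         path: str | Path | None = None):
    """Grouped bars of the proportion of calls per SSG size class.

    ``props``: rows indexed by size class, one column per group (e.g.
    condition).
    """
    fig, ax = plt.subplots(figsize=(5, 3.5))
    props.plot.bar(ax=ax, width=0.8)
    ax.set_xlabel("sonar sound group size")
    ax.set_ylabel("proportion of calls")
    ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    if path:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig


def plot_fingerprint(hist: np.ndarray, pre_edges: np.ndarray, post_edges: np.ndarray,
                     title: str = "", path: str | Path | None = None):
    """Pre- vs post-IPI density with the pre = post diagonal marked."""
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.pcolormesh(pre_edges, post_edges, hist.T, cmap="magma_r")
    lim = [pre_edges[0], pre_edges[-1]]
    ax.plot(lim, lim, color="0.6", lw=1)
    ax.set_xlabel("pre-IPI (ms)")
    ax.set_ylabel("post-IPI (ms)")
    ax.set_title(title)
    if path:
        fig.savefig(path, bbox_inches="tight")
        plt.close(fig)
    return fig
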