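"""Figure helpers: dual-axis scan curves, ranking bars, distance profiles,
correlation heat maps.  All functions return the matplotlib Figure."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

from .assays import RestraintRanking, ScanResult
from .correlation import CorrelationMatrix


def scan_curve(result: ScanResult, x: str, out_path=None, mu_col: str = "mu_mean"):
    """Normalized target function (left axis) and mu (right axis) vs the
    scanned condition."""
    df = result.summary
    fig, ax1 = plt.subplots(figsize=(5, 3.2))
    ax1.plot(df[x], df["normalized_target_function_mean"], "o-", color="tab:blue", label="norm. target function")
    ax1.set_xlabel(x)
    ax1.set_ylabel("normalized target function (A$^2$)", color="tab:blue")
    ax2 = ax1.twinx()
    if mu_col in df:
        ax2.plot(df[x], df[mu_col], "s-", color="tab:orange", label="structural correlation")
        sd = mu_col.replace("_mean", "_std")
        if sd in df and df[sd].notna().any():
            ax2.errorbar(df[x], df[mu_col], yerr=df[sd], fmt="none", ecolor="tab:orange", alpha=0.5)
    ax2.set_ylabel(r"structural correlation $\mu$", color="tab:orange")
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
    return fig


def ranking_bar(ranking: RestraintRanking, out_path=None, highlight: int = 20):
    """Sorted leave-one-out mu values with the full-set baseline dashed."""
    df = ranking.table
    n = len(df)
    colors = ["tab:green"] * min(highlight, n) + ["0.6"] * max(n - 2 * highlight, 0) + ["tab:red"] * min(highlight, n - min(highlight, n))
    fig, ax = plt.subplots(figsize=(6, 3.2))
    ax.bar(np.arange(n), df["mu_without"], color=colors[:n], width=1.0)
    ax.axhline(ranking.baseline_mu, ls="--", color="k", lw=1, label="all restraints")
    ax.set_xlabel("restraints sorted by $\\mu$ after removal")
    ax.set_ylabel(r"$\mu$ without restraint")
    ax.legend(frameon=False)
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
    return fig


def profile_plot(profile: pd.DataFrame, out_path=None):
    fig, ax = plt.subplots(figsize=(5, 3.2))
    ax.plot(profile["mean_distance"], profile["mean_correlation"], "o-")
    ax.set_xlabel(r"mean C$\alpha$-C$\alpha$ distance (A)")
    ax.set_ylabel("mean structural correlation")
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
    return fig


def correlation_heatmap(matrix: CorrelationMatrix, out_path=None):
    fig, ax = plt.subplots(figsize=(4.2, 3.6))
    im = ax.imshow(matrix.A, vmin=0, vmax=1, cmap="viridis", origin="lower")
    ax.set_xlabel("residue")
    ax.set_ylabel("residue")
    fig.colorbar(im, ax=ax, label="adjusted mutual information")
    fig.tight_layout()
    if out_path:
        fig.savefig(out_path, dpi=150)
    return fig
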