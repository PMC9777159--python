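"""Diagnostic plots: goodness-of-fit quartet, NPDE, VPC, PTA heatmaps."""
from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd
from scipy import stats


def gof_quartet(table: pd.DataFrame, path: str) -> None:
    """DV vs PRED, DV vs IPRED, CWRES vs time, CWRES vs PRED.

    ``table`` is the frame returned by :func:`neopkpd.diagnostics.cwres`.
    """
    fig, axes = plt.subplots(2, 2, figsize=(9, 8))
    for ax, x, xlab in (
        (axes[0, 0], table["pred"], "PRED (mg/L)"),
        (axes[0, 1], table["ipred"], "IPRED (mg/L)"),
    ):
        ax.scatter(x, table["dv_mg_L"], s=14, alpha=0.7, edgecolors="none")
        lim = max(float(x.max()), float(table["dv_mg_L"].max())) * 1.05
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel(xlab)
        ax.set_ylabel("DV (mg/L)")
    for ax, x, xlab in (
        (axes[1, 0], table["time_h"], "Time (h)"),
        (axes[1, 1], table["pred"], "PRED (mg/L)"),
    ):
        ax.scatter(x, table["cwres"], s=14, alpha=0.7, edgecolors="none")
        ax.axhline(0.0, color="k", ls="--", lw=1)
        ax.axhline(2.0, color="grey", ls=":", lw=1)
        ax.axhline(-2.0, color="grey", ls=":", lw=1)
        ax.set_xlabel(xlab)
        ax.set_ylabel("CWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def npde_plots(npde_values: np.ndarray, path: str) -> None:
    """Histogram with the N(0,1) density and a QQ plot."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    ax1.hist(npde_values, bins=15, density=True, alpha=0.7)
    grid = np.linspace(-3.5, 3.5, 200)
    ax1.plot(grid, stats.norm.pdf(grid), "k-", lw=1.5)
    ax1.set_xlabel("NPDE")
    ax1.set_ylabel("Density")
    stats.probplot(npde_values, dist="norm", plot=ax2)
    ax2.set_title("")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def vpc_plot(table: pd.DataFrame, path: str) -> None:
    """Observed percentile lines over simulation-based confidence bands."""
    fig, ax = plt.subplots(figsize=(7, 5))
    mid = 0.5 * (table["t_lo"] + table["t_hi"])
    for p, color in (("5", "tab:blue"), ("50", "tab:red"), ("95", "tab:blue")):
        ax.fill_between(
            mid, table[f"sim_p{p}_lo"], table[f"sim_p{p}_hi"],
            alpha=0.25, color=color,
        )
        ax.plot(mid, table[f"obs_p{p}"], "-o", color=color, ms=4,
                label=f"observed P{p}")
    ax.set_xlabel("Time since last dose (h)")
    ax.set_ylabel("Concentration (mg/L)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def pta_heatmaps(grid: pd.DataFrame, path: str, target_percent: float = 70.0) -> None:
    """One PTA heatmap (dose x infusion duration, per frequency) per GA group."""
    groups = list(dict.fromkeys(grid["ga_group"]))
    intervals = sorted(grid["interval_h"].unique())
    fig, axes = plt.subplots(
        len(groups), len(intervals),
        figsize=(5 * len(intervals), 4 * len(groups)),
        squeeze=False,
    )
    for gi, group in enumerate(groups):
        for ii, tau in enumerate(intervals):
            ax = axes[gi, ii]
            sub = grid[(grid["ga_group"] == group) & (grid["interval_h"] == tau)]
            pivot = sub.pivot(
                index="dose_mg_per_kg", columns="infusion_h", values="pta_percent"
            )
            im = ax.imshow(
                pivot.values, origin="lower", aspect="auto",
                vmin=0, vmax=100, cmap="viridis",
            )
            ax.set_xticks(range(len(pivot.columns)), [f"{c:g}" for c in pivot.columns])
            ax.set_yticks(range(len(pivot.index)), [f"{i:g}" for i in pivot.index])
            ax.set_xlabel("Infusion (h)")
            ax.set_ylabel("Dose (mg/kg)")
            ax.set_title(f"GA {group} wk, q{tau:g}h")
            for (r, c), val in np.ndenumerate(pivot.values):
                ax.text(c, r, f"{val:.0f}",
                        ha="center", va="center",
                        color="w" if val < target_percent else "k", fontsize=8)
    fig.colorbar(im, ax=axes.ravel().tolist(), label="PTA (%)")
    fig.savefig(path, dpi=120)
    plt.close(fig)
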