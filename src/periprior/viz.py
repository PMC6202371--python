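"""Diagnostic figures: bias curves, fitted-vs-measured, parameter bars."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

__all__ = ["plot_bias_curves", "plot_fit_scatter", "plot_parameter_bars"]

_COLORS = {"visual": "tab:red", "proprioceptive": "black"}


def plot_bias_curves(bias: pd.DataFrame, path) -> None:
    """Group-mean signed bias (% of disparity) vs signed disparity, one panel
    per hand-visibility condition."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.6), sharey=True)
    for ax, vis in zip(axes, ("visible", "invisible")):
        sub = bias[(bias["visibility"] == vis) & (bias["disparity_mm"] != 0)]
        for modality, g in sub.groupby("modality"):
            cell = g.groupby("disparity_mm")["bias_pct"]
            mean = cell.mean()
            sem = cell.std(ddof=1) / np.sqrt(cell.size())
            ax.errorbar(mean.index, mean, yerr=sem, marker="o",
                        color=_COLORS[modality], label=modality)
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_title(f"hand {vis}")
        ax.set_xlabel("disparity m_p - m_v (mm)")
    axes[0].set_ylabel("bias (% of disparity)")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_fit_scatter(residuals: pd.DataFrame, path,
                     model: str = "coupling_prior") -> None:
    """Model residuals (% of disparity) vs disparity magnitude per condition."""
    sub = residuals[residuals["model"] == model]
    fig, axes = plt.subplots(1, 2, figsize=(8.5, 4), sharex=True, sharey=True)
    for ax, vis in zip(axes, ("visible", "invisible")):
        g = sub[sub["visibility"] == vis]
        for modality, gg in g.groupby("modality"):
            cell = gg.groupby("magnitude_mm")["residual_pct"]
            mean = cell.mean()
            sem = cell.std(ddof=1) / np.sqrt(cell.size())
            ax.errorbar(mean.index, mean, yerr=sem, marker="o",
                        color=_COLORS[modality], label=modality)
        ax.axhline(0, color="grey", lw=0.5)
        ax.set_title(f"hand {vis}")
        ax.set_xlabel("|disparity| (mm)")
    axes[0].set_ylabel("residual (% of disparity)")
    axes[0].legend(frameon=False)
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_parameter_bars(contrast: pd.DataFrame, path) -> None:
    """Group mean +/- SEM of lambda and sigma_c per visibility condition."""
    fig, axes = plt.subplots(1, 2, figsize=(7, 3.5))
    for ax, param, unit in zip(axes, ("lam", "sigma_c"), ("", " (mm)")):
        row = contrast[contrast["parameter"] == param].iloc[0]
        means = [row["mean_visible"], row["mean_invisible"]]
        sems = [row["sem_visible"], row["sem_invisible"]]
        ax.bar(["visible", "invisible"], means, yerr=sems,
               color=["tab:blue", "tab:orange"], capsize=4)
        ax.set_title(f"{param}{unit}  (t={row['t_paired']:.2f})")
    fig.tight_layout()
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    fig.savefig(path, dpi=150)
    plt.close(fig)
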