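"""Static plot exports: dose-stratified VPC bands and GOF panels."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

__all__ = ["plot_vpc", "plot_gof"]


def plot_vpc(vpc_table: pd.DataFrame, path, observed_col: str = "observed_S") -> Path:
    """One panel per arm: 90% prediction band, predicted median, observed KM."""
    path = Path(path)
    arms = list(pd.unique(vpc_table["arm"]))
    ncol = min(len(arms), 4)
    nrow = int(np.ceil(len(arms) / ncol))
    fig, axes = plt.subplots(
        nrow, ncol, figsize=(3.2 * ncol, 2.6 * nrow), sharex=True, sharey=True,
        squeeze=False,
    )
    for ax, arm in zip(axes.ravel(), arms):
        grp = vpc_table[vpc_table["arm"] == arm]
        t = grp["time_h"] / 24.0
        ax.fill_between(t, grp["pred_lo_S"], grp["pred_hi_S"], alpha=0.3, lw=0)
        ax.plot(t, grp["pred_median_S"], "--", lw=1.2, label="predicted median")
        if observed_col in grp:
            ax.step(t, grp[observed_col], where="post", color="k", lw=1.2, label="observed KM")
        ax.set_title(str(arm), fontsize=9)
        ax.set_ylim(-0.02, 1.02)
    for ax in axes[-1]:
        ax.set_xlabel("time (days)")
    for row in axes:
        row[0].set_ylabel("S(t)")
    axes[0, 0].legend(fontsize=7, loc="lower left")
    for ax in axes.ravel()[len(arms):]:
        ax.set_visible(False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path


def plot_gof(gof_table: pd.DataFrame, path) -> Path:
    """Obs vs population/individual predictions; IWRES vs ipred and time."""
    path = Path(path)
    fig, axes = plt.subplots(2, 2, figsize=(7.2, 6.4))
    for ax, col, label in (
        (axes[0, 0], "pred_population", "population prediction"),
        (axes[0, 1], "pred_individual", "individual prediction"),
    ):
        ax.loglog(gof_table[col], gof_table["observed"], ".", ms=3, alpha=0.5)
        lims = [gof_table["observed"].min() * 0.8, gof_table["observed"].max() * 1.2]
        ax.plot(lims, lims, "k-", lw=0.8)
        ax.set_xlabel(f"{label} (mm$^3$)")
        ax.set_ylabel("observed (mm$^3$)")
    for ax, x, label in (
        (axes[1, 0], gof_table["pred_individual"], "individual prediction (mm$^3$)"),
        (axes[1, 1], gof_table["time_h"] / 24.0, "time (days)"),
    ):
        ax.plot(x, gof_table["iwres"], ".", ms=3, alpha=0.5)
        ax.axhline(0.0, color="k", lw=0.8)
        ax.set_xlabel(label)
        ax.set_ylabel("IWRES")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
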