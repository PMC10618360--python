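"""Figures mirroring the standard result surfaces: population traces with
+/-SE per condition per alignment, switch vs no-switch peak scatterplots,
and per-bin correlation bars.  All figures are drawn from the emitted CSV
tables so every plotted value is re-derivable from them."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd

CONDITION_COLORS = {"no_switch": "#7b2d8b", "switch": "#888888"}


def plot_population(pop_csv: str | Path, out_path: str | Path) -> Path:
    df = pd.read_csv(pop_csv, comment="#")
    fig, ax = plt.subplots(figsize=(5, 3.2))
    for cond, color in CONDITION_COLORS.items():
        mean = df[f"mean_{cond}"]
        se = df[f"se_{cond}"]
        ax.plot(df.time_ms, mean, color=color, label=cond.replace("_", "-"))
        ax.plot(df.time_ms, mean + se, color=color, ls=":", lw=0.8)
        ax.plot(df.time_ms, mean - se, color=color, ls=":", lw=0.8)
    ax.axvline(0.0, color="k", lw=0.8)
    ax.set_xlabel("time (ms)")
    ax.set_ylabel("normalized activity")
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return Path(out_path)


def plot_peak_scatter(peaks_csv: str | Path, out_path: str | Path) -> Path:
    df = pd.read_csv(peaks_csv, comment="#")
    wide = df.pivot(index="cell", columns="condition")
    fig, axes = plt.subplots(1, 2, figsize=(6.4, 3.2))
    for ax, epoch in zip(axes, ("visual", "motor")):
        x = wide[(f"{epoch}_peak_hz", "no_switch")]
        y = wide[(f"{epoch}_peak_hz", "switch")]
        lim = max(x.max(), y.max()) * 1.05
        ax.plot([0, lim], [0, lim], "k-", lw=0.6)
        ax.plot(x, y, "o", ms=4, mfc="none", color="#333333")
        ax.set_xlim(0, lim)
        ax.set_ylim(0, lim)
        ax.set_xlabel(f"no-switch {epoch} peak (spk/s)")
        ax.set_ylabel(f"switch {epoch} peak (spk/s)")
        ax.set_aspect("equal")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return Path(out_path)


def plot_buildup_correlation(corr_csv: str | Path, out_path: str | Path) -> Path:
    df = pd.read_csv(corr_csv, comment="#")
    colors = np.where(
        df.flag == "+", "black", np.where(df.flag == "-", "red", "#cccccc")
    )
    fig, ax = plt.subplots(figsize=(5, 3.0))
    ax.bar(df.bin_center_ms, df.r, width=20.0, color=colors)
    ax.axhline(0.0, color="k", lw=0.8)
    ax.set_xlabel("time before saccade onset (ms)")
    ax.set_ylabel("Pearson r (switch vs no-switch)")
    ax.set_ylim(-1, 1)
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return Path(out_path)
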