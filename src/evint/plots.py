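"""Figure helpers for the standard summaries.

Each function returns a matplotlib Figure; callers decide whether to save
or show.  Colors encode noise level throughout (darker = noisier).
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def _noise_colors(levels):
    cmap = plt.get_cmap("viridis_r")
    return {p: cmap(0.15 + 0.8 * i / max(len(levels) - 1, 1))
            for i, p in enumerate(sorted(levels))}


def plot_accuracy_by_time(df: pd.DataFrame) -> plt.Figure:
    """Held-out accuracy vs readout time, one panel per regime, one line
    per noise level (the supervised sweep summary)."""
    regimes = sorted(df.regime.unique())
    fig, axes = plt.subplots(1, len(regimes), figsize=(4.5 * len(regimes), 3.5),
                             sharey=True, squeeze=False)
    colors = _noise_colors(df.noise.unique())
    for ax, regime in zip(axes[0], regimes):
        sub = df[df.regime == regime]
        for noise, cell in sub.groupby("noise"):
            m = cell.groupby("depth").accuracy.mean()
            ax.plot(m.index, m.values, "o-", color=colors[noise],
                    label=f"{int(100 * noise)}% noise")
        ax.set_xlabel("readout time (steps)")
        ax.set_title(f"{regime} noise")
    axes[0, 0].set_ylabel("accuracy")
    axes[0, -1].legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_behavior(summary: pd.DataFrame) -> plt.Figure:
    """Psychometric and chronometric panels from a behavioral summary."""
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(8, 3.5))
    s = summary.sort_values("signal_strength")
    ax1.errorbar(s.signal_strength, s.accuracy,
                 yerr=[s.accuracy - s.acc_ci_low, s.acc_ci_high - s.accuracy],
                 fmt="ko-")
    ax1.set_xscale("log")
    ax1.set_xlabel("signal strength (%)")
    ax1.set_ylabel("accuracy")
    ax2.errorbar(s.signal_strength, s.mean_obs, yerr=s.sem_obs, fmt="ko-")
    ax2.set_xscale("log")
    ax2.set_xlabel("signal strength (%)")
    ax2.set_ylabel("mean observations")
    fig.tight_layout()
    return fig


def plot_learning_curve(curve: pd.DataFrame, window: int = 50) -> plt.Figure:
    """Cumulative reward, fraction answered and accuracy over training."""
    fig, axes = plt.subplots(1, 3, figsize=(11, 3))
    roll = curve[["frac_answered", "accuracy"]].rolling(window, min_periods=1).mean()
    axes[0].plot(curve.env_steps, curve.cumulative_reward, "k-")
    axes[0].set_ylabel("cumulative reward")
    axes[1].plot(curve.env_steps, roll.frac_answered, "k-")
    axes[1].set_ylabel("fraction answered")
    axes[2].plot(curve.env_steps, roll.accuracy, "k-")
    axes[2].set_ylabel("accuracy")
    for ax in axes:
        ax.set_xlabel("environment steps")
    fig.tight_layout()
    return fig
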