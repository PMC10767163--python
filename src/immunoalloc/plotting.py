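"""Convenience plots over the CSV-producing pipelines.

Figures are a viewing layer only; all quantitative output lives in the
CSVs the presets write.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np


def plot_semelparous_surface(df):
    """r_i* against gamma, one panel per f, lines per M."""
    fs = sorted(df["f"].unique())
    fig, axes = plt.subplots(1, len(fs), figsize=(4 * len(fs), 3.2), sharey=True, squeeze=False)
    for ax, f in zip(axes[0], fs):
        sub = df[df["f"] == f]
        for M, grp in sub.groupby("M"):
            g = grp[grp["interior"]]
            if len(g):
                ax.plot(g["gamma"], g["r_i_star"], label=f"M={M:g}")
        ax.set_title(f"f = {f:g}")
        ax.set_xlabel(r"$\gamma$")
    axes[0][0].set_ylabel(r"$r_i^*$")
    if df["M"].nunique() <= 8:
        axes[0][-1].legend(fontsize=7)
    fig.tight_layout()
    return fig


def plot_survivors(run, fit=None):
    """Survivor counts on a log scale, optionally with the fitted decay."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    t = run.times
    mask = run.survivors > 0
    ax.semilogy(t[mask], run.survivors[mask], "o", ms=4, label="survivors")
    if fit is not None:
        s0 = run.survivors[mask][0]
        ax.semilogy(t[mask], s0 * np.exp(-fit.m_emergent * (t[mask] - t[mask][0])),
                    "-", label=f"$M_{{emergent}}$ = {fit.m_emergent:.3f}")
    ax.set_xlabel("breeding period t")
    ax.set_ylabel("alive individuals")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig


def plot_policy(policy, t: int = 1, gain_index: int | None = None):
    """Optimal allocations against reserves at a given period."""
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    v = policy.grid.values
    if policy.stochastic:
        lev = gain_index if gain_index is not None else policy.gain.n_levels // 2
        ri = policy.r_i_star[t - 1, :, lev]
        ro = policy.r_o_star[t - 1, :, lev]
    else:
        ri = policy.r_i_star[t - 1]
        ro = policy.r_o_star[t - 1]
    ax.plot(v, ri, label=r"$r_i^*$")
    ax.plot(v, ro, label=r"$r_o^*$")
    ax.set_xlabel("reserves r")
    ax.set_ylabel("allocation")
    ax.set_title(f"t = {t}")
    ax.legend(fontsize=8)
    fig.tight_layout()
    return fig
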