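"""The two report figures: cumulative incidence of OMT and the ΔGDMT summary."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
import pandas as pd


def plot_cumulative_incidence(curves: dict, path=None, horizon: int = 84):
    """Step plot of per-arm cumulative incidence with pointwise CI bands.

    ``curves`` maps arm label -> DataFrame with columns time, incidence,
    ci_low, ci_high (as returned by ``stats.cumulative_incidence``).
    """
    fig, ax = plt.subplots(figsize=(6, 4))
    colors = {"DC": "tab:red", "USUAL": "tab:blue"}
    for arm, df in curves.items():
        df = pd.DataFrame(df)
        ax.step(df["time"], df["incidence"], where="post",
                label=arm, color=colors.get(arm))
        ax.fill_between(df["time"], df["ci_low"], df["ci_high"],
                        step="post", alpha=0.15, color=colors.get(arm))
    ax.set_xlim(0, horizon)
    ax.set_ylim(0, 1)
    ax.set_xlabel("days since randomization")
    ax.set_ylabel("cumulative incidence of OMT")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_delta_gdmt(scores: pd.DataFrame, path=None):
    """Box plot of the per-patient change in GDMT score by arm."""
    fig, ax = plt.subplots(figsize=(4.5, 4))
    groups = [scores.loc[scores.arm == a, "delta_gdmt"] for a in ("USUAL", "DC")]
    ax.boxplot(groups, tick_labels=["usual care", "DC"], showmeans=True)
    ax.axhline(0, color="grey", lw=0.5)
    ax.set_ylabel("ΔGDMT score (follow-up − baseline)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
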