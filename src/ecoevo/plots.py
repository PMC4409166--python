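"""Diagnostic figures: yield vs richness, and observed vs additive yields."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

_ENV_COLORS = {"beech": "tab:orange", "ph5": "tab:green", "spruce": "tab:red"}


def plot_yield_vs_richness(yields, design, path=None):
    """Community yield against richness per environment, one panel per week."""
    richness = design.groupby("composition_id")["richness"].first()
    frame = yields.merge(richness.rename("richness"), left_on="composition_id", right_index=True)
    weeks = sorted(frame["week"].unique())
    fig, axes = plt.subplots(1, len(weeks), figsize=(4 * len(weeks), 3.5), sharey=True, squeeze=False)
    for ax, week in zip(axes[0], weeks):
        sub = frame[frame["week"] == week]
        for env, grp in sub.groupby("environment"):
            jitter = np.random.default_rng(0).normal(0, 0.03, len(grp))
            ax.scatter(
                np.log(grp["richness"]) + jitter,
                grp["yield"],
                s=8,
                alpha=0.5,
                color=_ENV_COLORS.get(env, "gray"),
                label=env,
            )
        ax.set_xlabel("log richness")
        ax.set_title(f"week {week}")
    axes[0][0].set_ylabel("yield (OD 595)")
    axes[0][0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig


def plot_observed_vs_additive(frame, path=None):
    """Observed community yields against the additive expectation at both
    weeks, with the 1:1 additive-growth line."""
    fig, axes = plt.subplots(1, 2, figsize=(8, 3.8), sharex=True, sharey=True)
    panels = [("week 0", "add0", "A0"), ("week 5", "add5_mono", "A5")]
    for ax, (title, xcol, ycol) in zip(axes, panels):
        for env, grp in frame.groupby("environment"):
            ax.scatter(
                grp[xcol], grp[ycol], s=10, alpha=0.6, color=_ENV_COLORS.get(env, "gray"), label=env
            )
        lim = max(frame[[xcol, ycol]].max().max() for _, xcol, ycol in panels) * 1.05
        ax.plot([0, lim], [0, lim], "k--", lw=1)
        ax.set_xlabel("additive expectation (sum of monoculture yields)")
        ax.set_title(title)
    axes[0].set_ylabel("observed community yield")
    axes[0].legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
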