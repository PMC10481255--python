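"""Coefficient (forest) plots for association results."""

from __future__ import annotations

import pandas as pd


def forest_plot(results: pd.DataFrame, ax=None, title: str | None = None):
    """Standardized-estimate forest plot of one block's tidy results.

    One row per (outcome, term): point estimate with 95% CI whiskers,
    FDR-significant terms marked with an asterisk.  Returns the axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 0.35 * len(results) + 1.2))
    labels = [f"{r.outcome}: {r.term}" for r in results.itertuples()]
    y = range(len(results))[::-1]
    ax.errorbar(
        results["estimate"],
        list(y),
        xerr=[
            results["estimate"] - results["ci_lo"],
            results["ci_hi"] - results["estimate"],
        ],
        fmt="o",
        color="k",
        ecolor="gray",
        capsize=2,
    )
    for yi, (_, row) in zip(y, results.iterrows()):
        if row.get("q_flag", False):
            ax.annotate("*", (row["ci_hi"], yi), textcoords="offset points", xytext=(4, -3))
    ax.axvline(0.0, color="0.6", lw=0.8, ls="--")
    ax.set_yticks(list(y))
    ax.set_yticklabels(labels, fontsize=8)
    ax.set_xlabel("standardized estimate (SD outcome per SD predictor)")
    if title:
        ax.set_title(title)
    return ax
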