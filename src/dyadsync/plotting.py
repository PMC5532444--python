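"""Minimal DRP plotting: mean recurrence per lag by condition, real
curves solid and surrogate baselines dashed."""

from __future__ import annotations

from typing import Optional

import pandas as pd

__all__ = ["plot_drp"]

_COLORS = {"affiliative": "tab:green", "argumentative": "tab:red"}


def plot_drp(drps: pd.DataFrame, ax=None, title: Optional[str] = None):
    """Plot condition-mean DRP curves from the long-format table.

    Real rows are drawn solid, surrogate rows dashed, colored by
    conversation type.  Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    df = drps.copy()
    if "source" not in df.columns:
        df["source"] = "real"
    for (conv, source), g in df.groupby(["conv_type", "source"]):
        prof = g.groupby("lag")["rr"].mean()
        ax.plot(
            prof.index, prof.to_numpy(),
            color=_COLORS.get(conv, "gray"),
            linestyle="-" if source == "real" else "--",
            label=f"{conv} ({source})",
        )
    ax.set_xlabel("lag (samples at 10 Hz)")
    ax.set_ylabel("recurrence rate")
    if title:
        ax.set_title(title)
    ax.legend(fontsize=8)
    return ax
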