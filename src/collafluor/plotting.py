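"""Best-effort time-course plots: bars with SEM whiskers and significance letters."""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

_LETTERS = {"P<0.001": "a", "P<0.01": "b", "P<0.05": "c", "ns": ""}


def plot_timecourse(
    summary: pd.DataFrame,
    contrasts: pd.DataFrame | None = None,
    metric: str = "intensity",
    out: str | Path | None = None,
):
    """Grouped bar chart of group/day mean +/- SEM for one metric.

    Per-day significance letters (a: P<0.001, b: P<0.01, c: P<0.05) are
    drawn above the treated group's bar when a contrasts table is given.
    Returns the matplotlib figure.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    sub = summary[summary.metric == metric]
    days = sorted(sub.day.unique())
    groups = sorted(sub.group.unique())
    width = 0.8 / max(len(groups), 1)
    fig, ax = plt.subplots(figsize=(7, 4))
    x = np.arange(len(days))
    for gi, group in enumerate(groups):
        cell = sub[sub.group == group].set_index("day").reindex(days)
        pos = x + (gi - (len(groups) - 1) / 2) * width
        ax.bar(pos, cell["mean"], width=width * 0.9, yerr=cell["sem"],
               capsize=2, label=group.replace("_", " "))
        if contrasts is not None and group == "laser_treated":
            csub = contrasts
            if "metric" in csub.columns:
                csub = csub[csub.metric == metric]
            for day, p, m, s in zip(cell.index, pos, cell["mean"], cell["sem"]):
                row = csub[csub.day == day]
                if len(row):
                    letter = _LETTERS.get(row.label.iloc[0], "")
                    if letter:
                        ax.text(p, (m + (s or 0)) * 1.02, letter,
                                ha="center", fontsize=9)
    ax.set_xticks(x)
    ax.set_xticklabels([str(d) for d in days])
    ax.set_xlabel("days post-wounding")
    ax.set_ylabel(metric)
    ax.legend(fontsize=8)
    fig.tight_layout()
    if out is not None:
        fig.savefig(out, dpi=150)
    return fig
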