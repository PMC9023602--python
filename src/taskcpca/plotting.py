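"""Quick-look plots for fitted solutions (matplotlib, Agg-safe)."""

from __future__ import annotations

import numpy as np


def plot_scree(results, ax=None, max_components: int = 20):
    """Scree plot of variance explained with the retained count marked."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    ve = results.variance_explained[:max_components]
    ax.plot(np.arange(1, len(ve) + 1), ve, "o-", ms=4)
    ax.axvline(results.retained, color="0.4", ls="--", lw=1)
    ax.set_xlabel("component")
    ax.set_ylabel("fraction of task-related variance")
    ax.set_title(f"scree (retained {results.retained})")
    return ax


def plot_group_curves(group_curves, component: str, ax=None):
    """Mean +/- SE response curves for one component, by group and
    event type (expects the frame from :func:`aggregate_curves`)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(5, 3.5))
    sel = group_curves[group_curves["component"] == component]
    for (grp, etype), cell in sel.groupby(["group", "event_type"]):
        ls = "--" if etype.startswith("non-threat") else "-"
        ax.errorbar(
            cell["lag_time_s"], cell["mean"], yerr=cell["se"],
            label=f"{grp} {etype}", ls=ls, lw=1.2, capsize=2,
        )
    ax.axhline(0, color="0.7", lw=0.8)
    ax.set_xlabel("time after event onset (s)")
    ax.set_ylabel("component score")
    ax.set_title(component)
    ax.legend(fontsize=6)
    return ax
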