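"""Basic plots: guild-metric method comparison and pair-score variability."""

from __future__ import annotations

import pandas as pd

from .uncertainty import UncertaintyResult


def plot_metric_comparison(edna_metrics: pd.DataFrame, tef_metrics: pd.DataFrame, ax=None):
    """Side-by-side bars of per-guild metric values for the two methods.

    Both frames are samples x guilds in the same unit; bars show the
    cross-sample mean per guild and method.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(8, 4))
    guilds = [g for g in edna_metrics.columns if g in tef_metrics.columns]
    summary = pd.DataFrame(
        {"eDNA": edna_metrics[guilds].mean(), "TEF": tef_metrics[guilds].mean()}
    )
    summary.plot.bar(ax=ax)
    ax.set_ylabel("mean metric value")
    ax.set_xlabel("guild")
    return ax


def plot_pair_scores(results: list[UncertaintyResult], ax=None):
    """Boxplots of the pairwise index scores of replicate-rich sites."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.boxplot(
        [r.pair_scores.to_numpy() for r in results],
        tick_labels=[str(r.site) for r in results],
    )
    ax.set_ylabel("index score over sample pairs")
    return ax
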