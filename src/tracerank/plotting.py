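"""Stacked-bar view of per-criterion strengths and weaknesses.

Each alternative gets a bar decomposed by criterion: segments above zero
are criteria on which it out-performs the field (positive weighted
unicriterion net flow), segments below zero are weaknesses.  Segment
heights are w_k * phi_k(t), so they sum to the overall net flow.
"""

from __future__ import annotations

import pandas as pd

__all__ = ["plot_unicriterion_decomposition"]


def plot_unicriterion_decomposition(
    phi: pd.DataFrame, weights: pd.Series, order: list[str] | None = None, ax=None
):
    """Plot the weighted unicriterion net-flow decomposition.

    Parameters
    ----------
    phi:
        Per-alternative, per-criterion unicriterion net flows
        (:func:`tracerank.promethee.unicriterion_net_flows`).
    weights:
        Normalized criterion weights.
    order:
        Alternative display order (default: descending total net flow).
    ax:
        Existing matplotlib axes; a new figure is created otherwise.
    """
    import matplotlib.pyplot as plt  # deferred: plotting is optional

    contrib = phi * weights
    if order is None:
        order = contrib.sum(axis=1).sort_values(ascending=False).index
    contrib = contrib.loc[order]
    if ax is None:
        _, ax = plt.subplots(figsize=(max(6, 0.6 * len(contrib)), 4))
    bottom_pos = pd.Series(0.0, index=contrib.index)
    bottom_neg = pd.Series(0.0, index=contrib.index)
    x = range(len(contrib))
    for crit in contrib.columns:
        vals = contrib[crit]
        base = bottom_pos.where(vals >= 0, bottom_neg)
        ax.bar(x, vals, bottom=base, label=crit)
        bottom_pos += vals.clip(lower=0)
        bottom_neg += vals.clip(upper=0)
    ax.axhline(0.0, color="black", linewidth=0.8)
    ax.set_xticks(list(x), contrib.index, rotation=60, ha="right", fontsize=8)
    ax.set_ylabel("weighted unicriterion net flow")
    ax.legend(fontsize=8)
    ax.figure.tight_layout()
    return ax
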