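"""Basic summary plots: MSE curves and paired-regime K comparisons.

Styling is deliberately minimal; these are working plots, not figure
reproductions.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_mse_curves", "plot_regime_comparison"]


def plot_mse_curves(curves, labels=None, ax=None):
    """Overlay sample-entropy-vs-scale curves.

    ``curves`` is an iterable of :class:`~ephapsim.complexity.MSECurve`;
    missing scales are simply gaps in the line.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    curves = list(curves)
    labels = labels if labels is not None else [None] * len(curves)
    for curve, label in zip(curves, labels):
        ax.plot(curve.taus, curve.se, label=label)
    ax.set_xlabel("scale factor τ")
    ax.set_ylabel("sample entropy")
    if any(lbl is not None for lbl in labels):
        ax.legend()
    return ax


def plot_regime_comparison(comparisons, x: str = "omega", ax=None):
    """Mean K per condition for both regimes, from a sweep comparison table.

    ``comparisons`` is the DataFrame returned by
    :func:`ephapsim.experiments.sweep`; ``x`` names the swept column.
    Significance stars are annotated above each condition pair.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    tab = comparisons.sort_values(x)
    xs = tab[x].to_numpy()
    ax.plot(xs, tab["mean_K_on"], "o-", color="tab:red", label="ephaptic on")
    ax.plot(xs, tab["mean_K_off"], "s-", color="tab:blue", label="ephaptic off")
    top = np.maximum(tab["mean_K_on"], tab["mean_K_off"])
    for xi, yi, star in zip(xs, top, tab["stars"]):
        ax.annotate(star, (xi, yi), textcoords="offset points", xytext=(0, 6),
                    ha="center", fontsize=9)
    ax.set_xlabel(x)
    ax.set_ylabel("mean complexity K")
    ax.legend()
    return ax
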