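"""Report figures for the statistical battery.

A compact significance heatmap: rows are features, columns are the
comparisons (rest-vs-task change within EH/NEH, EH-vs-NEH at rest/task)
and the ROC scopes (rest/task/diff AUC), drawn per analysis level.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .features import FEATURE_NAMES


def _stars(p: float) -> str:
    for thr, mark in ((1e-4, "****"), (1e-3, "***"), (1e-2, "**"), (0.05, "*")):
        if p < thr:
            return mark
    return "ns"


def plot_significance_heatmap(tests: pd.DataFrame, rocs: pd.DataFrame, title: str = ""):
    """Figure-style summary of test significance and ROC-AUC per feature.

    Returns a matplotlib Figure with two panels: -log10 p for the four
    group/condition comparisons, and the AUC of each ROC scope annotated
    with its significance level.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    comparisons = [
        "rest-vs-task within EH",
        "rest-vs-task within NEH",
        "EH-vs-NEH at rest",
        "EH-vs-NEH at task",
    ]
    scopes = ["rest", "task", "diff"]
    features = [f for f in FEATURE_NAMES if f in set(tests.get("feature", []))] or FEATURE_NAMES

    pmat = np.full((len(features), len(comparisons)), np.nan)
    for i, feat in enumerate(features):
        for j, comp in enumerate(comparisons):
            sel = tests[(tests.feature == feat) & (tests.comparison == comp)]
            if len(sel):
                pmat[i, j] = -np.log10(max(sel.p_value.iloc[0], 1e-16))

    amat = np.full((len(features), len(scopes)), np.nan)
    pann = np.empty((len(features), len(scopes)), dtype=object)
    for i, feat in enumerate(features):
        for j, scope in enumerate(scopes):
            sel = rocs[(rocs.feature == feat) & (rocs.scope == scope)]
            if len(sel):
                amat[i, j] = sel.auc.iloc[0]
                pann[i, j] = _stars(sel.p_vs_chance.iloc[0])

    fig, (ax1, ax2) = plt.subplots(
        1, 2, figsize=(10, 0.45 * len(features) + 2),
        gridspec_kw={"width_ratios": [4, 3]},
    )
    im1 = ax1.imshow(pmat, aspect="auto", cmap="viridis")
    ax1.set_xticks(range(len(comparisons)))
    ax1.set_xticklabels(comparisons, rotation=45, ha="right", fontsize=8)
    ax1.set_yticks(range(len(features)))
    ax1.set_yticklabels(features, fontsize=8)
    ax1.set_title("-log10 p")
    fig.colorbar(im1, ax=ax1, shrink=0.8)

    im2 = ax2.imshow(amat, aspect="auto", cmap="coolwarm", vmin=0, vmax=1)
    ax2.set_xticks(range(len(scopes)))
    ax2.set_xticklabels(scopes, fontsize=8)
    ax2.set_yticks(range(len(features)))
    ax2.set_yticklabels([])
    ax2.set_title("ROC-AUC (EH positive)")
    for i in range(len(features)):
        for j in range(len(scopes)):
            if pann[i, j]:
                ax2.text(j, i, pann[i, j], ha="center", va="center", fontsize=7)
    fig.colorbar(im2, ax=ax2, shrink=0.8)
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    return fig
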