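"""Thin plotting conveniences over the data-only result tables."""

from __future__ import annotations

import numpy as np
import pandas as pd

__all__ = ["manhattan_plot"]


def manhattan_plot(manhattan: pd.DataFrame, threshold: float | None = None, ax=None):
    """Gene-level Manhattan plot from a (chrom, pos, neg_log10_p) table.

    Returns the matplotlib axes; matplotlib is imported lazily so the
    analysis stack has no hard plotting dependency.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(10, 3.5))
    chroms = sorted(manhattan["chrom"].unique(), key=lambda c: int(c))
    offset = 0
    ticks = []
    for i, chrom in enumerate(chroms):
        sub = manhattan[manhattan["chrom"] == chrom].sort_values("pos")
        x = offset + np.arange(len(sub))
        ax.scatter(x, sub["neg_log10_p"], s=8,
                   color="#1f77b4" if i % 2 == 0 else "#ff7f0e")
        ticks.append((offset + len(sub) / 2, chrom))
        offset += len(sub)
    if threshold is not None:
        ax.axhline(-np.log10(threshold), linestyle=":", color="grey")
    ax.set_xticks([t[0] for t in ticks])
    ax.set_xticklabels([t[1] for t in ticks], fontsize=7)
    ax.set_xlabel("chromosome")
    ax.set_ylabel(r"$-\log_{10}(p)$")
    return ax
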