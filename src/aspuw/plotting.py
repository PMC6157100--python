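"""Optional plot rendering; the tested artifact is the table."""

from __future__ import annotations

from .scan import ScanResult, manhattan_table

__all__ = ["plot_manhattan"]


def plot_manhattan(scan: ScanResult, column: str = "aspuw_p", ax=None,
                   threshold: float | None = None):
    """Manhattan plot of gene-level -log10 p-values.

    Returns the matplotlib Axes.  ``threshold`` (a p-value) draws the
    genome-wide significance line; defaults to the scan's Bonferroni
    threshold when testable genes exist.
    """
    import matplotlib.pyplot as plt
    import numpy as np

    table = manhattan_table(scan, column=column)
    if ax is None:
        _, ax = plt.subplots(figsize=(9, 3))
    for i, (chrom, sub) in enumerate(table.groupby("chrom", sort=True)):
        ax.scatter(sub["midpoint"], sub["neglog10_p"], s=6,
                   color=f"C{i % 2}", label=None)
    if threshold is None and scan.n_testable:
        threshold = scan.threshold
    if threshold is not None:
        ax.axhline(-np.log10(threshold), color="red", ls="--", lw=0.8)
    ax.set_xlabel("position")
    ax.set_ylabel(r"$-\log_{10} p$")
    return ax
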