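"""Static diagnostic figures for the three analyses."""

from __future__ import annotations

import numpy as np

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
from scipy import stats  # noqa: E402


def plot_spatial_null(logvmrs, null, ax=None):
    """Histogram of logVMRs with the fitted Gaussian null overlaid."""
    if ax is None:
        _, ax = plt.subplots()
    x = np.asarray(logvmrs, dtype=float)
    x = x[np.isfinite(x)]
    ax.hist(x, bins=60, density=True, alpha=0.6, label="logVMR")
    grid = np.linspace(x.min(), x.max(), 400)
    ax.plot(grid, stats.norm.pdf(grid, null.mode, null.sigma), label="Gaussian null")
    ax.axvline(null.mode, ls="--", lw=0.8)
    ax.set_xlabel("logVMR")
    ax.set_ylabel("density")
    ax.legend()
    return ax


def plot_enrichment_scatter(results, q_max=0.001, ax=None):
    """-log10(q) vs log2(max LE) per cluster, labeled clusters annotated."""
    if ax is None:
        _, ax = plt.subplots()
    ax.scatter(results["neg_log10_q"], results["log2_max_le"],
               c=np.where(results["labeled"], "tab:red", "tab:gray"))
    ax.axvline(-np.log10(q_max), ls="--", lw=0.8)
    for cluster, row in results[results["labeled"]].iterrows():
        ax.annotate(str(cluster), (row["neg_log10_q"], row["log2_max_le"]),
                    fontsize=7, xytext=(3, 3), textcoords="offset points")
    ax.set_xlabel("-log10(q)")
    ax.set_ylabel("log2(max lobule enrichment)")
    return ax


def plot_log10m_ecdf(curves: dict, ax=None):
    """Overlay ECDFs of log10(m) for several population pairs."""
    if ax is None:
        _, ax = plt.subplots()
    for label, curve in curves.items():
        ax.step(curve["value"], curve["cdf"], where="post", label=label)
    ax.set_xlabel("log10(m)")
    ax.set_ylabel("cumulative fraction of genes")
    ax.legend()
    return ax
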