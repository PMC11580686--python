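"""Optional plotting helpers (matplotlib required only here).

Each function draws one of the standard QC views onto a new or supplied
Axes and returns it; callers save or show the figure themselves. A
non-interactive backend is fine — nothing here needs a display.
"""

from __future__ import annotations

import numpy as np

from .evenness import CoverageHistogram
from .hic_qc import LsdHistogram, PowerLawFit


def _get_axes(ax):
    if ax is not None:
        return ax
    import matplotlib.pyplot as plt

    _, ax = plt.subplots()
    return ax


def plot_lsd_distribution(hist: LsdHistogram, fit: PowerLawFit | None = None, ax=None):
    """Percentage frequency vs link-separation distance on log-log axes,
    with the fitted power-law tail overlaid when given."""
    ax = _get_axes(ax)
    pct = hist.percentages()
    idx = np.array(sorted(pct))
    centers = (idx + 0.5) * hist.bin_width
    ax.loglog(centers, [pct[i] for i in idx], ".", ms=2, label="data")
    if fit is not None:
        xs = np.logspace(np.log10(fit.d_min), np.log10(fit.d_max), 50)
        scale = 100.0 * hist.bin_width / max(hist.total, 1)
        ax.loglog(xs, scale * 10**fit.intercept * xs**-fit.exponent, "-",
                  label=f"b = {fit.exponent:.2f}, R² = {fit.r_squared:.3f}")
        ax.legend()
    ax.set_xlabel("link-separation distance (bp)")
    ax.set_ylabel("frequency (%)")
    return ax


def plot_coverage_distribution(hist: CoverageHistogram, ax=None, label=None):
    """Site count vs depth, normalized to the modal value."""
    ax = _get_axes(ax)
    depths = np.array(sorted(hist.counts))
    counts = np.array([hist.counts[int(d)] for d in depths], dtype=float)
    ax.plot(depths, counts / counts.max(), label=label)
    ax.set_xlabel("depth")
    ax.set_ylabel("fraction of maximal site count")
    if label:
        ax.legend()
    return ax


def plot_molecule_length_curve(curve: np.ndarray, ax=None, label=None):
    """Accumulated length fraction vs molecule length (descending)."""
    ax = _get_axes(ax)
    ax.semilogx(curve[:, 0], curve[:, 1], label=label)
    ax.set_xlabel("molecule length (bp)")
    ax.set_ylabel("accumulated fraction of molecule length")
    if label:
        ax.legend()
    return ax


def plot_contact_map(mat, bins, ax=None, log: bool = True):
    """Dense rendering of a (small) binned contact matrix; darker means
    higher contact density. Intended for toy or coarse-binned matrices."""
    ax = _get_axes(ax)
    dense = mat.toarray().astype(float)
    dense = dense + dense.T - np.diag(np.diag(dense))
    if log:
        dense = np.log1p(dense)
    ax.imshow(dense, cmap="Greys", origin="upper")
    edges = bins.groupby("chromosome", sort=False)["bin_id"].min().to_numpy()
    for e in edges[1:]:
        ax.axhline(e - 0.5, lw=0.5, color="steelblue")
        ax.axvline(e - 0.5, lw=0.5, color="steelblue")
    ax.set_xlabel("bin")
    ax.set_ylabel("bin")
    return ax
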