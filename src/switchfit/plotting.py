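"""Histogram + fitted-curve plots for trait distributions."""

from __future__ import annotations

import numpy as np

from .mixfit import BinnedDistribution, MixtureFit, _gauss_curve


def plot_fit(
    binned: BinnedDistribution,
    fit_single: MixtureFit = None,
    fit_double: MixtureFit = None,
    ax=None,
    decompose: bool = True,
):
    """Plot a binned trait distribution with fitted Gaussian curves.

    The double fit, when given, is drawn with its two component
    sub-distributions so the lean and heavy sub-populations are visible.
    Returns the matplotlib Axes.
    """
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    ax.bar(binned.midpoints, binned.counts, width=binned.widths,
           color="0.8", edgecolor="0.5", label="observed")
    grid = np.linspace(binned.edges[0], binned.edges[-1], 400)
    total = binned.n_effective
    width = binned.bin_width

    def curve(f):
        out = np.zeros_like(grid)
        for c in f.components:
            if c.amplitude is not None:
                out += _gauss_curve(grid, c.amplitude, c.mu, c.sigma)
            else:
                out += total * width * c.weight * c.density(grid)
        return out

    if fit_single is not None:
        ax.plot(grid, curve(fit_single), color="gray", lw=2,
                label=f"single Gaussian (R²={fit_single.r2:.3f})")
    if fit_double is not None:
        ax.plot(grid, curve(fit_double), color="tab:blue", lw=2,
                label=f"double Gaussian (R²={fit_double.r2:.3f})")
        if decompose:
            for c, style in zip(fit_double.components, ("--", ":")):
                if c.amplitude is not None:
                    y = _gauss_curve(grid, c.amplitude, c.mu, c.sigma)
                else:
                    y = total * width * c.weight * c.density(grid)
                ax.plot(grid, y, style, color="tab:green", lw=1.5)
    ax.set_xlabel("trait")
    ax.set_ylabel("count")
    ax.legend(frameon=False)
    return ax
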