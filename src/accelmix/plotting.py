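"""Optional figure export: index histogram with fitted mixture curves."""

from __future__ import annotations

from pathlib import Path

import numpy as np

from .mixture import MixtureFit, mixture_pdf, normal_pdf


def plot_mixture(pool: np.ndarray, fit: MixtureFit, path: str | Path,
                 bin_width_g: float = 0.02) -> None:
    """Histogram of the in-play index with the fitted mixture overlaid.

    Green: full mixture; blue: low-intensity component; red: high-intensity
    component.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    hi = float(np.max(pool))
    bins = np.arange(0.0, hi + 2 * bin_width_g, bin_width_g)
    ax.hist(pool, bins=bins, density=True, color="0.8", edgecolor="0.6")
    x = np.linspace(0.0, hi + 2 * bin_width_g, 400)
    ax.plot(x, fit.w_low * normal_pdf(x, fit.mu_low, fit.sigma_low),
            color="tab:blue", label="low component")
    ax.plot(x, fit.w_high * normal_pdf(x, fit.mu_high, fit.sigma_high),
            color="tab:red", label="high component")
    ax.plot(x, mixture_pdf(x, fit), color="tab:green", lw=2, label="mixture")
    ax.set_xlabel("acceleration index (G)")
    ax.set_ylabel("density (1/G)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_scatter_matrix(table, path: str | Path) -> None:
    """Scatter matrix of the five mixture features, colored by group."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import pandas.plotting as pdp

    from .signal_io import GMM_FEATURES

    groups = table.groups
    colors = table.data["group"].map(dict(zip(groups, ["tab:blue", "tab:orange"])))
    axes = pdp.scatter_matrix(table.data[GMM_FEATURES], color=colors,
                              figsize=(9, 9), diagonal="hist")
    fig = axes[0, 0].get_figure()
    fig.suptitle(" vs ".join(str(g) for g in groups))
    fig.savefig(path, dpi=150)
    plt.close(fig)
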