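"""Basic diagnostic figure: k_obs vs accessible lipid with the fitted curve."""

from __future__ import annotations

from typing import Sequence

import numpy as np

from .fitting import KineticFitResult
from .traces import KobsPoint

__all__ = ["plot_kobs_fit"]


def plot_kobs_fit(points: Sequence[KobsPoint], fit: KineticFitResult, path=None):
    """Scatter the k_obs table with error bars and overlay the fitted model.

    Returns the matplotlib figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    acc = np.array([p.lipid_accessible for p in points])
    kobs = np.array([p.k_obs for p in points])
    se = np.array([p.se if p.se is not None else 0.0 for p in points])

    grid_acc = np.linspace(0, 1.05 * acc.max(), 200)
    basis_scale = 1.0 if fit.convention.lipid_basis == "accessible" else 1.0 / fit.leaflet_factor
    p = fit.params
    e0 = fit.convention.protein_conc
    s = p.c1 * grid_acc * basis_scale
    pred = np.sqrt(p.k_on**2 * (e0 - s) ** 2 + p.k_off**2 + 2 * p.k_on * p.k_off * (e0 + s))

    fig, ax = plt.subplots(figsize=(5, 4))
    ax.errorbar(acc, kobs, yerr=se, fmt="o", color="k", capsize=3, label="observed")
    ax.plot(grid_acc, pred, "-", color="tab:red", label="relaxation model")
    ax.set_xlabel("accessible lipid (μM)")
    ax.set_ylabel(r"$k_\mathrm{obs}$ (s$^{-1}$)")
    ax.legend(frameon=False)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
    return fig
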