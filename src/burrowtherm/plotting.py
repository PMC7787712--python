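"""Diagnostic scatter plots for the fitted analysis.

Two views, one per regression family: thermoregulation capacity
(Tb - S) against surface temperature, and against burrow cooling
capacity (B - S), with the per-group least-squares lines overlaid.
Purely diagnostic; no analysis result depends on them.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .data import SizeClass  # noqa: E402

GROUP_COLORS = {
    SizeClass.small_female: "tab:red",
    SizeClass.large_female: "tab:orange",
    SizeClass.small_male: "tab:blue",
    SizeClass.large_male: "tab:purple",
}


def _scatter_with_fits(results, xcol: str, fits, xlabel: str, ax=None,
                       path=None):
    if ax is None:
        fig, ax = plt.subplots(figsize=(7, 5))
    else:
        fig = ax.figure
    df = results.frame
    for g, color in GROUP_COLORS.items():
        sub = df[df["size_class"] == g.value].dropna(subset=[xcol])
        if len(sub) == 0:
            continue
        x = sub[xcol].to_numpy()
        ax.scatter(x, sub["thermoreg_capacity_c"], s=12, alpha=0.5,
                   color=color, label=g.value.replace("_", " "))
        fit = fits.get(g)
        if fit is not None:
            xs = np.linspace(x.min(), x.max(), 50)
            ax.plot(xs, fit.predict(xs), color=color, lw=1.5)
    ax.axhline(0.0, color="0.6", lw=0.8, ls=":")
    ax.set_xlabel(xlabel)
    ax.set_ylabel("thermoregulation capacity  Tb − S  (°C)")
    ax.legend(fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(Path(path), dpi=120)
        plt.close(fig)
    return ax


def plot_capacity_vs_surface(results, ax=None, path=None):
    """Tb - S against S with the per-group regression lines."""
    return _scatter_with_fits(results, "surface_temp_c",
                              results.capacity_fits,
                              "surface temperature  S  (°C)", ax=ax,
                              path=path)


def plot_axes(results, ax=None, path=None):
    """The thermoregulation axes: Tb - S against B - S per group."""
    return _scatter_with_fits(results, "cooling_capacity_c",
                              results.axes_fits,
                              "cooling capacity  B − S  (°C)", ax=ax,
                              path=path)
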