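"""Figures for the occupancy analysis.

Both plots follow the survey's conventions: the distance axis is reversed so
the range limit (d = 0) sits at the right, marked by a dashed vertical line.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402


def plot_rates(eq, path=None):
    """Colonisation and extinction probability curves over distance."""
    fig, axes = plt.subplots(1, 2, figsize=(9, 3.5), sharex=True)
    for ax, curve, label in zip(axes, (eq.c_hat, eq.e_hat),
                                ("colonisation $c$", "extinction $e$")):
        ax.plot(eq.dist_km, curve, color="k")
        ax.axvline(0.0, linestyle="--", color="grey")
        ax.set_xlim(eq.dist_km.max(), eq.dist_km.min())
        ax.set_xlabel("distance to range limit (km)")
        ax.set_ylabel(label)
        ax.set_ylim(0, 1)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_occupancy(comp, eq=None, path=None):
    """Observed occupancy with its confidence band and the predicted
    equilibrium occupancy n*, with the bootstrap envelope when present."""
    fig, ax = plt.subplots(figsize=(6, 4))
    ax.fill_between(comp.dist_km, comp.band_lo, comp.band_hi,
                    color="0.85", label=f"{int(comp.level * 100)}% band ($n_{{obs}}$)")
    ax.plot(comp.dist_km, comp.n_obs, color="k", label="observed occupancy $n_{obs}$")
    ax.plot(comp.dist_km, comp.n_star, color="C3", label="equilibrium $n^*$")
    if eq is not None and eq.envelope_lo is not None:
        ax.plot(comp.dist_km, eq.envelope_lo, color="C3", lw=0.7, alpha=0.6)
        ax.plot(comp.dist_km, eq.envelope_hi, color="C3", lw=0.7, alpha=0.6)
    ax.axvline(0.0, linestyle="--", color="grey")
    ax.set_xlim(comp.dist_km.max(), comp.dist_km.min())
    ax.set_xlabel("distance to range limit (km)")
    ax.set_ylabel("occupancy of suitable plots")
    ax.set_ylim(0, 1)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
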