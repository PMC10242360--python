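"""Publication-style figures: CE plane, CEAC, price-reduction curve."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np


def ce_plane(bootstrap, effect_measure: str = "ly", path=None, ax=None):
    """Scatter of bootstrap (incremental effect, incremental cost) pairs."""
    de = bootstrap.effect(effect_measure)
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 5))
    else:
        fig = ax.figure
    ax.scatter(de, bootstrap.dc, s=8, alpha=0.5, edgecolors="none")
    ax.axhline(0, color="grey", lw=0.8)
    ax.axvline(0, color="grey", lw=0.8)
    unit = "LYG" if effect_measure == "ly" else "QALY"
    ax.set_xlabel(f"Incremental effectiveness ({unit})")
    ax.set_ylabel("Incremental cost (CAD)")
    ax.set_title(f"Cost-effectiveness plane ({bootstrap.B} bootstrap samples)")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax


def ceac_plot(curve, path=None, ax=None):
    """Cost-effectiveness acceptability curve."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    ax.plot(curve.wtp / 1000.0, curve.probability)
    unit = "LYG" if curve.effect_measure == "ly" else "QALY"
    ax.set_xlabel(f"Willingness-to-pay (thousand CAD per {unit})")
    ax.set_ylabel("Probability cost-effective")
    ax.set_ylim(-0.02, 1.02)
    ax.set_title("Cost-effectiveness acceptability curve")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax


def price_reduction_plot(price_table, effect_measure: str = "qaly",
                         path=None, ax=None):
    """ICER against the drug-of-interest price-reduction fraction."""
    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 4))
    else:
        fig = ax.figure
    col = "icer_per_qaly" if effect_measure == "qaly" else "icer_per_ly"
    ax.plot(100 * np.asarray(price_table["fraction"]), price_table[col],
            marker="o", ms=3)
    unit = "QALY" if effect_measure == "qaly" else "LYG"
    ax.set_xlabel("Price reduction (%)")
    ax.set_ylabel(f"ICER (CAD per {unit})")
    ax.set_title("Drug price-reduction sensitivity")
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
        plt.close(fig)
    return ax
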