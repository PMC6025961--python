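"""Optional plotting helpers.  Numeric pipeline outputs never depend on
these; every function returns the matplotlib Figure and can save to file."""

from __future__ import annotations

from typing import List, Optional

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402
import pandas as pd  # noqa: E402

from .snapshots import HillFit, SnapshotSample, classify_positive  # noqa: E402

__all__ = ["snapshot_histogram", "fraction_metabolite_overlay",
           "dose_response_plot", "lineage_kymograph", "genealogy_heat_tree"]


def _save(fig, path):
    if path is not None:
        fig.savefig(path, dpi=150, bbox_inches="tight")
    return fig


def snapshot_histogram(sample: SnapshotSample, k: float = 2.0, path=None):
    """Fluorescence histogram with the high-expressing tail shaded."""
    res = classify_positive(sample.values, k=k)
    fig, ax = plt.subplots(figsize=(5, 3.2))
    bins = np.histogram_bin_edges(sample.values, bins=60)
    ax.hist(sample.values, bins=bins, color="0.7")
    ax.axvline(res.threshold, color="crimson", ls="--",
               label=f"mean + {k:g} SD")
    ax.axvspan(res.threshold, bins[-1], color="crimson", alpha=0.15)
    ax.set_xlabel(f"{sample.reporter_name} fluorescence (AU)")
    ax.set_ylabel("cells")
    ax.set_title(f"t = {sample.t:g} min, OD {sample.od:.2f}, "
                 f"{100 * res.fraction_positive:.1f}% positive")
    ax.legend(frameon=False)
    return _save(fig, path)


def fraction_metabolite_overlay(fractions: pd.DataFrame, env: pd.DataFrame,
                                path=None):
    """Fraction-positive time courses over the acetate/acetoin curves."""
    fig, ax = plt.subplots(figsize=(6, 3.5))
    ax2 = ax.twinx()
    for rep, sub in fractions.groupby("reporter"):
        ax.plot(sub["t_min"], 100 * sub["fraction_positive"], label=f"{rep}+")
    ax2.plot(env["t_min"], env["acetate_mM"], color="crimson", ls="--",
             label="acetate")
    ax2.plot(env["t_min"], env["acetoin_mM"], color="seagreen", ls="--",
             label="acetoin")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("positive cells (%)")
    ax2.set_ylabel("concentration (mM)")
    ax.legend(loc="upper left", frameon=False)
    ax2.legend(loc="upper right", frameon=False)
    return _save(fig, path)


def dose_response_plot(doses, fractions, fit: Optional[HillFit] = None,
                       path=None):
    fig, ax = plt.subplots(figsize=(4.5, 3.2))
    ax.plot(doses, fractions, "o", color="k")
    if fit is not None and not fit.non_identifiable:
        grid = np.linspace(0, max(doses), 200)
        ax.plot(grid, fit.predict(grid), color="crimson",
                label=f"Hill: K={fit.K:.1f} mM, h={fit.h:.2f}")
        ax.legend(frameon=False)
    ax.set_xlabel("acetate (mM)")
    ax.set_ylabel("alsS+ fraction")
    return _save(fig, path)


def lineage_kymograph(lineage: pd.DataFrame, channel: int, column="f_alsS",
                      path=None):
    """Kymograph-style strip of one growth channel (position x time)."""
    sub = lineage[lineage["channel_id"] == channel]
    fig, ax = plt.subplots(figsize=(7, 2.5))
    # stack cells per frame in id (birth) order: schematic queue, mother at 0
    slot = sub.groupby("frame")["cell_id"].rank(method="first").to_numpy() - 1
    sc = ax.scatter(sub["t_min"], slot, c=sub[column], s=8, cmap="viridis")
    fig.colorbar(sc, ax=ax, label=f"{column} (AU)")
    ax.set_xlabel("time (min)")
    ax.set_ylabel("queue slot")
    ax.set_title(f"channel {channel}")
    return _save(fig, path)


def genealogy_heat_tree(tree, path=None):
    """Genealogy with per-cell mean alsS expression as node colour."""
    g = tree.graph
    xpos, ypos = {}, {}
    leaves = sorted(tree.leaves(), key=lambda n: g.nodes[n]["birth_t"])
    for i, leaf in enumerate(leaves):
        ypos[leaf] = i
    for node in reversed(list(_topo(tree))):
        if node not in ypos:
            kids = list(g.successors(node))
            ypos[node] = np.mean([ypos[k] for k in kids])
        xpos[node] = g.nodes[node]["birth_t"]
    fig, ax = plt.subplots(figsize=(6, 4))
    expr = [g.nodes[n]["mean_f_alsS"] for n in g.nodes]
    vmin, vmax = min(expr), max(expr)
    for a, b in g.edges:
        ax.plot([g.nodes[a]["end_t"], xpos[b]], [ypos[a], ypos[b]],
                color="0.6", lw=0.8, zorder=1)
    for n in g.nodes:
        ax.plot([xpos[n], g.nodes[n]["end_t"]], [ypos[n], ypos[n]],
                color="0.3", lw=0.8, zorder=1)
    sc = ax.scatter([xpos[n] for n in g.nodes], [ypos[n] for n in g.nodes],
                    c=expr, cmap="coolwarm", vmin=vmin, vmax=vmax, s=18,
                    zorder=2)
    fig.colorbar(sc, ax=ax, label="mean alsS fluorescence (AU)")
    ax.set_xlabel("time (min)")
    ax.set_yticks([])
    return _save(fig, path)


def _topo(tree):
    import networkx as nx
    return nx.topological_sort(tree.graph)
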