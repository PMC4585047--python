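"""Signed network plots: red positive edges, blue negative, width ∝ |r|."""

from __future__ import annotations

from typing import Optional

from .connectivity import CorrelationMatrix, edge_list


def plot_network(
    corr: CorrelationMatrix,
    min_abs_r: float = 0.0,
    ax=None,
    title: Optional[str] = None,
    seed: int = 0,
):
    """Draw the thresholded signed co-activation network.

    Returns the matplotlib Axes.  Layout is a seeded spring embedding, so
    paired plots of two groups are directly comparable.
    """
    import matplotlib.pyplot as plt
    import networkx as nx

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    g = nx.Graph()
    g.add_nodes_from(corr.regions)
    edges = edge_list(corr, min_abs_r)
    for _, row in edges.iterrows():
        g.add_edge(row["region_a"], row["region_b"], r=float(row["r"]))
    pos = nx.spring_layout(g, seed=seed)
    widths = [3.0 * abs(g.edges[e]["r"]) for e in g.edges]
    colors = ["tab:red" if g.edges[e]["r"] >= 0 else "tab:blue" for e in g.edges]
    nx.draw_networkx_edges(g, pos, ax=ax, width=widths, edge_color=colors, alpha=0.7)
    nx.draw_networkx_nodes(g, pos, ax=ax, node_color="lightgray", node_size=500)
    nx.draw_networkx_labels(g, pos, ax=ax, font_size=8)
    if title:
        ax.set_title(title)
    ax.set_axis_off()
    return ax
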