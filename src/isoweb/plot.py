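"""Food-web visualisation: directed graph with node size scaled by the
number of links a taxon forms and arrow width by interaction strength.
"""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import networkx as nx

from .types import PredationMatrix


def build_graph(matrix: PredationMatrix, link_threshold: float = 0.0) -> nx.DiGraph:
    """Directed graph with prey → predator edges weighted by contribution."""
    g = nx.DiGraph()
    vals = matrix.values
    nodes = list(dict.fromkeys(list(vals.index) + list(vals.columns)))
    g.add_nodes_from(nodes)
    for prey in vals.index:
        for pred in vals.columns:
            w = float(vals.loc[prey, pred])
            if w > link_threshold:
                g.add_edge(prey, pred, weight=w)
    return g


def plot_web(
    matrix: PredationMatrix,
    path: str | Path,
    seed: int = 0,
    link_threshold: float = 0.0,
    base_node_size: float = 120.0,
    base_edge_width: float = 0.5,
) -> nx.DiGraph:
    """Render the web to ``path`` (PNG/SVG by extension); returns the graph.

    Node size grows linearly with total degree and edge width with the
    diet contribution; the spring layout is seeded, so the same matrix
    and seed give identical coordinates.
    """
    if matrix.values.size == 0:
        raise ValueError("cannot plot an empty predation matrix")
    g = build_graph(matrix, link_threshold)
    pos = nx.spring_layout(g, seed=seed)
    for n, (x, y) in pos.items():
        g.nodes[n]["pos"] = (float(x), float(y))
        g.nodes[n]["size"] = base_node_size * (1 + g.degree(n))
    sizes = [g.nodes[n]["size"] for n in g.nodes]
    widths = [base_edge_width + 4.0 * g.edges[e]["weight"] for e in g.edges]
    fig, ax = plt.subplots(figsize=(8, 6))
    nx.draw_networkx_nodes(g, pos, node_size=sizes, node_color="#4a90a4", ax=ax)
    nx.draw_networkx_edges(
        g, pos, width=widths, arrows=True, arrowsize=12,
        node_size=sizes, ax=ax, edge_color="#555555",
    )
    nx.draw_networkx_labels(g, pos, font_size=7, ax=ax)
    ax.set_axis_off()
    fig.tight_layout()
    try:
        fig.savefig(path, dpi=150)
    except OSError as exc:
        raise OSError(f"failed to write web plot to {path}: {exc}") from exc
    finally:
        plt.close(fig)
    return g


__all__ = ["build_graph", "plot_web"]
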