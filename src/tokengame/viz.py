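"""Weighted player-network construction, layout and export.

The game is rendered as an undirected weighted graph: an edge joins two
players who exchanged at least one token in either direction, weighted by
the total exchange count between them. Node attributes carry the group
label, an influence-based size (mean of the two standardised influence
scores by default) and the player's self-giving count — self-giving is a
node property, not a loop edge. Layout is force-directed
(Fruchterman-Reingold) with edge weight as attraction strength, so heavily
exchanging players sit close together and the two groups typically separate.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import networkx as nx
import numpy as np

from .game import GameData, GameValidationError, cumulative_matrix
from .influence import InfluenceTable

__all__ = ["build_network", "layout_positions", "export_graph", "render_network"]


def build_network(game: GameData, influence: InfluenceTable | None = None,
                  t: int | None = None, size_stat: str = "mean") -> nx.Graph:
    """Build the weighted player graph at round ``t`` (default: final round).

    Edge (i, j), i < j, has weight Y_ij + Y_ji (tokens exchanged in either
    direction) and exists only when that weight is positive. Nodes carry
    ``group``, ``self_giving`` and ``influence_size`` (1.0 when no influence
    table is supplied). Total edge weight plus total self-giving equals
    n_players * t.
    """
    t = game.n_rounds if t is None else t
    if not (0 <= t <= game.n_rounds):
        raise GameValidationError(f"round out of range: {t}")
    Y = cumulative_matrix(game, t).Y
    sizes = (influence.node_sizes(size_stat) if influence is not None else None)

    G = nx.Graph()
    for i in range(1, game.n_players + 1):
        G.add_node(i,
                   group=game.groups.label_of(i),
                   self_giving=int(Y[i - 1, i - 1]),
                   influence_size=float(sizes[i]) if sizes is not None else 1.0)
    sym = Y + Y.T
    for i in range(1, game.n_players + 1):
        for j in range(i + 1, game.n_players + 1):
            w = int(sym[i - 1, j - 1])
            if w > 0:
                G.add_edge(i, j, weight=w)
    return G


def layout_positions(graph: nx.Graph, seed: int = 0,
                     iterations: int = 100) -> dict[int, tuple[float, float]]:
    """Deterministic Fruchterman-Reingold coordinates, weight-attracted."""
    if graph.number_of_nodes() == 0:
        raise GameValidationError("cannot lay out an empty graph")
    pos = nx.spring_layout(graph, weight="weight", seed=int(seed),
                           iterations=iterations)
    return {node: (float(x), float(y)) for node, (x, y) in pos.items()}


def export_graph(graph: nx.Graph, positions: Mapping[int, tuple[float, float]],
                 path: str | Path) -> Path:
    """Write GraphML with all node/edge attributes plus x, y coordinates."""
    out = Path(path)
    g = graph.copy()
    for node, (x, y) in positions.items():
        g.nodes[node]["x"] = float(x)
        g.nodes[node]["y"] = float(y)
    nx.write_graphml(g, out)
    return out


def render_network(graph: nx.Graph, positions: Mapping[int, tuple[float, float]],
                   path: str | Path) -> Path:
    """Optional raster rendering: colour by group, edge darkness by weight,
    node size by influence, border width by self-giving."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    groups = sorted({d["group"] for _, d in graph.nodes(data=True)})
    palette = ["#7b4fa6", "#3a8f5d", "#c05a2e", "#3566a5"]
    colours = [palette[groups.index(d["group"]) % len(palette)]
               for _, d in graph.nodes(data=True)]
    sizes = np.array([d["influence_size"] for _, d in graph.nodes(data=True)])
    sizes = 300.0 * sizes / max(sizes.mean(), 1e-9)
    borders = np.array([d["self_giving"] for _, d in graph.nodes(data=True)], float)
    max_border = borders.max() if borders.size and borders.max() > 0 else 1.0
    weights = np.array([d["weight"] for _, _, d in graph.edges(data=True)], float)

    fig, ax = plt.subplots(figsize=(6, 6))
    if weights.size:
        shade = 0.15 + 0.85 * weights / weights.max()
        nx.draw_networkx_edges(graph, positions, ax=ax,
                               edge_color=[(0, 0, 0, a) for a in shade],
                               width=1.5)
    nx.draw_networkx_nodes(graph, positions, ax=ax, node_color=colours,
                           node_size=sizes, edgecolors="black",
                           linewidths=0.5 + 3.0 * borders / max_border)
    nx.draw_networkx_labels(graph, positions, ax=ax, font_size=8)
    ax.set_axis_off()
    out = Path(path)
    fig.savefig(out, dpi=150, bbox_inches="tight")
    plt.close(fig)
    return out
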