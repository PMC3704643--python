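"""Directed MPA graph: neighborhoods, clusters and betweenness centrality.

Edges run source -> destination for every nonzero off-diagonal connection
probability; self-loops (local retention) are recorded separately and
excluded from degrees, paths and clustering. Shortest paths are hop-count
paths (edges unweighted regardless of the connection probability), and
betweenness is the sum over ordered node pairs (k, l), k != i != l, of the
fraction of shortest k->l paths passing through i.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .connectivity import ConnectivityMatrix


@dataclass
class MPAGraph:
    """Directed graph over MPAs plus self-loop flags."""

    graph: nx.DiGraph
    self_loops: set

    @property
    def nodes(self):
        return list(self.graph.nodes)

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()


def build_graph(C: ConnectivityMatrix) -> MPAGraph:
    """Edge j -> i iff c(i, j) > 0 and i != j; self-loops stored separately."""
    g = nx.DiGraph()
    ids = list(C.mpa_ids)
    g.add_nodes_from(ids)
    c = C.c
    self_loops = set()
    for i in range(C.n):
        for j in range(C.n):
            if c[i, j] > 0:
                if i == j:
                    self_loops.add(ids[i])
                else:
                    g.add_edge(ids[j], ids[i], weight=float(c[i, j]))
    return MPAGraph(graph=g, self_loops=self_loops)


def neighborhood_sizes(g: MPAGraph) -> pd.DataFrame:
    """Per-MPA downstream (out) and upstream (in) neighborhood sizes.

    Also classifies nodes: isolated (both 0), pure source (no upstream),
    pure sink (no downstream), interior otherwise.
    """
    rows = []
    for node in g.nodes:
        down = g.graph.out_degree(node)
        up = g.graph.in_degree(node)
        if down == 0 and up == 0:
            cls = "isolated"
        elif up == 0:
            cls = "pure_source"
        elif down == 0:
            cls = "pure_sink"
        else:
            cls = "interior"
        rows.append({"mpa_id": node, "downstream": down, "upstream": up,
                     "class": cls})
    return pd.DataFrame(rows).set_index("mpa_id")


def strong_clusters(g: MPAGraph) -> dict:
    """Strongly connected components: mutual directed reachability classes.

    Pure sources, pure sinks and isolated nodes each form singleton
    clusters. Returns ``{node: cluster_label}`` with labels ordered by
    decreasing cluster size.
    """
    comps = sorted(nx.strongly_connected_components(g.graph),
                   key=lambda s: (-len(s), min(s)))
    return {node: k for k, comp in enumerate(comps) for node in comp}


def weak_clusters(g: MPAGraph) -> dict:
    """Connected components after forgetting edge direction."""
    comps = sorted(nx.weakly_connected_components(g.graph),
                   key=lambda s: (-len(s), min(s)))
    return {node: k for k, comp in enumerate(comps) for node in comp}


def n_clusters(labels: dict) -> int:
    return len(set(labels.values()))


def betweenness(g: MPAGraph, normalized: bool = False) -> dict:
    """Betweenness centrality b(i) = sum_{k != l, both != i} s_kl(i)/s_kl.

    Hop-count shortest paths on the directed graph; pairs with no connecting
    path contribute nothing; endpoints are not counted as pass-through.
    Raw sums by default; ``normalized=True`` divides by (n-1)(n-2).
    """
    return nx.betweenness_centrality(g.graph, normalized=normalized)


def rank_nodes(g: MPAGraph) -> pd.DataFrame:
    """Full node-metric table sorted by betweenness (desc), ties by id."""
    b_raw = betweenness(g, normalized=False)
    n = g.n
    norm = (n - 1) * (n - 2) if n > 2 else 1
    nb = neighborhood_sizes(g)
    strong = strong_clusters(g)
    weak = weak_clusters(g)
    df = nb.copy()
    df["self_loop"] = [node in g.self_loops for node in df.index]
    df["strong_cluster"] = [strong[node] for node in df.index]
    df["weak_cluster"] = [weak[node] for node in df.index]
    df["betweenness"] = [b_raw[node] for node in df.index]
    df["betweenness_norm"] = df["betweenness"] / norm
    return (df.reset_index()
              .sort_values(["betweenness", "mpa_id"], ascending=[False, True],
                           kind="stable")
              .set_index("mpa_id"))


def export_edges(g: MPAGraph) -> pd.DataFrame:
    """Edge list (source, destination, connection probability)."""
    rows = [{"source": a, "destination": b, "c": d.get("weight", np.nan)}
            for a, b, d in g.graph.edges(data=True)]
    return pd.DataFrame(rows, columns=["source", "destination", "c"])


def to_dot(g: MPAGraph) -> str:
    """Minimal DOT export for visualization."""
    lines = ["digraph mpa {"]
    for node in g.nodes:
        shape = "doublecircle" if node in g.self_loops else "circle"
        lines.append(f'  "{node}" [shape={shape}];')
    for a, b in g.graph.edges:
        lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    return "\n".join(lines)
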