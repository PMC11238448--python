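"""High-resolution population networks from genetic distances.

Each individual becomes a node; edges connect k-nearest neighbours under
the genetic distance D = 1 - IBS.  The default union rule keeps an edge if
either endpoint selects the other among its k closest (so minimum degree is
k); a mutual-only variant is available.  Node attributes (population,
contribution score, F_ROH, admixture proportions) are attached for
rendering, and an edge-styling table maps lower distances to thicker edges.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import networkx as nx

from herdstruct.relationship import RelationshipMatrix


def knn_network(
    D: RelationshipMatrix,
    k: int = 10,
    mutual: bool = False,
) -> nx.Graph:
    """k-nearest-neighbour graph on a distance matrix.

    Neighbours are ranked by (distance, id) so ties break deterministically.
    With ``mutual=False`` (default) an edge is kept when either endpoint
    selects it; with ``mutual=True`` both must.
    """
    d = D.values
    ids = D.ids
    n = len(ids)
    if k >= n:
        raise ValueError(f"k={k} must be smaller than n={n}")
    graph = nx.Graph()
    for i, pid in enumerate(ids):
        graph.add_node(pid)
    selected: set[tuple[int, int]] = set()  # directed picks (i chose j)
    for i in range(n):
        order = sorted((d[i, j], ids[j], j) for j in range(n) if j != i)
        for _, _, j in order[:k]:
            selected.add((i, j))
    for i in range(n):
        for j in range(i + 1, n):
            a, b = (i, j) in selected, (j, i) in selected
            keep = (a and b) if mutual else (a or b)
            if keep:
                graph.add_edge(ids[i], ids[j], distance=float(d[i, j]))
    return graph


def annotate(
    graph: nx.Graph,
    populations: pd.Series | None = None,
    scores: pd.Series | None = None,
    roh_summary: pd.DataFrame | None = None,
    admixture_q: pd.DataFrame | None = None,
) -> nx.Graph:
    """Attach node attributes; raises naming any node missing from a table.

    Admixture proportions are stored as one scalar attribute per ancestry
    column (``q_<name>``) so the graph survives GraphML round trips.
    """
    nodes = list(graph.nodes)

    def check(index, what):
        missing = [n for n in nodes if n not in index]
        if missing:
            raise KeyError(f"{what} missing for node(s): {missing[:10]}")

    if populations is not None:
        check(populations.index, "population")
        nx.set_node_attributes(graph, populations.loc[nodes].to_dict(),
                               "population")
    if scores is not None:
        check(scores.index, "gc score")
        nx.set_node_attributes(graph, scores.loc[nodes].astype(float).to_dict(),
                               "gc")
    if roh_summary is not None:
        tab = roh_summary.set_index("id") if "id" in roh_summary else roh_summary
        check(tab.index, "F_ROH")
        nx.set_node_attributes(
            graph, tab.loc[nodes, "F_ROH_pct"].astype(float).to_dict(), "F_ROH")
    if admixture_q is not None:
        check(admixture_q.index, "admixture")
        for col in admixture_q.columns:
            nx.set_node_attributes(
                graph, admixture_q.loc[nodes, col].astype(float).to_dict(),
                f"q_{col}")
    return graph


def edge_weight_style(graph: nx.Graph) -> pd.DataFrame:
    """Per-edge rendering thickness: min-max normalised (1 - distance).

    Thickness decreases monotonically with distance; if all edges share one
    distance they all get thickness 1.
    """
    rows = [(u, v, d["distance"]) for u, v, d in graph.edges(data=True)]
    df = pd.DataFrame(rows, columns=["u", "v", "distance"])
    if not len(df):
        df["thickness"] = []
        return df
    sim = 1.0 - df["distance"]
    rng_ = sim.max() - sim.min()
    df["thickness"] = 1.0 if rng_ == 0 else (sim - sim.min()) / rng_
    return df


def write_graphml(graph: nx.Graph, path) -> None:
    nx.write_graphml(graph, path)


def write_edge_list(graph: nx.Graph, path) -> None:
    edge_weight_style(graph).to_csv(path, sep="\t", index=False)
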