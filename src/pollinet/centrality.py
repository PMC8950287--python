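"""Species centrality and composite keystone ranking.

Centralities are computed on the binary structure of the network, by
default as one graph over all interacting species (bipartite mode);
one-mode projections per trophic level are available as an alternative,
since both conventions circulate in the mutualistic-network literature.

Betweenness (BC) is shortest-path betweenness normalized by
``(n-1)(n-2)/2``; closeness (CC) is the un-rescaled convention
``1 / sum(geodesic distances to reachable vertices)``, which places values
of field-sized networks in the few-percent range. Unreachable pairs
contribute nothing; the fraction of reachable ordered pairs is reported
alongside. Isolated species carry degree 0 and undefined (None) BC/CC.

The keystone of a trophic level is the species with the best mean rank
across degree, BC and CC (ties broken by degree, then label).
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd

from .network import BipartiteNetwork
from .metrics import unweighted_degree

__all__ = ["CentralityTable", "centralities", "keystone_rank"]


@dataclass(frozen=True)
class CentralityTable:
    """Per-species degree/BC/CC per trophic level, plus reachability."""

    plants: pd.DataFrame  # index: species; columns: degree, bc, cc
    pollinators: pd.DataFrame
    graph_mode: str
    reachable_fraction: float

    def level(self, level: str) -> pd.DataFrame:
        if level == "plant":
            return self.plants
        if level == "pollinator":
            return self.pollinators
        raise ValueError(f"unknown trophic level {level!r}")


def _closeness(g: nx.Graph) -> dict:
    """CC(v) = 1 / sum of geodesic distances to vertices reachable from v."""
    out = {}
    for v in g:
        dists = nx.single_source_shortest_path_length(g, v)
        total = sum(d for u, d in dists.items() if u != v)
        out[v] = 1.0 / total if total > 0 else None
    return out


def _reachable_fraction(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    if n < 2:
        return 1.0
    reach = sum(len(nx.single_source_shortest_path_length(g, v)) - 1 for v in g)
    return reach / (n * (n - 1))


def centralities(net: BipartiteNetwork, graph_mode: str = "bipartite") -> CentralityTable:
    """Degree, betweenness and closeness for every species.

    Parameters
    ----------
    graph_mode : {"bipartite", "projection"}
        "bipartite" computes BC/CC on the single two-mode graph over all
        interacting species; "projection" computes them on the unweighted
        one-mode projection of each trophic level (species linked when they
        share at least one partner).
    """
    deg = unweighted_degree(net)
    g = nx.Graph()
    pnodes = [("P", p) for p in net.plant_labels]
    anodes = [("A", a) for a in net.pollinator_labels]
    g.add_nodes_from(pnodes, bipartite=0)
    g.add_nodes_from(anodes, bipartite=1)
    for i, p in enumerate(net.plant_labels):
        for j, a in enumerate(net.pollinator_labels):
            if net.weights[i, j] > 0:
                g.add_edge(("P", p), ("A", a))
    if g.number_of_nodes() == 0:
        raise ValueError("empty graph")

    if graph_mode == "bipartite":
        bc = nx.betweenness_centrality(g, normalized=True)
        cc = _closeness(g)
        reach = _reachable_fraction(g)
    elif graph_mode == "projection":
        gp = nx.bipartite.projected_graph(g, pnodes)
        ga = nx.bipartite.projected_graph(g, anodes)
        bc = {**nx.betweenness_centrality(gp, normalized=True),
              **nx.betweenness_centrality(ga, normalized=True)}
        cc = {**_closeness(gp), **_closeness(ga)}
        np_, na = gp.number_of_nodes(), ga.number_of_nodes()
        reach = (_reachable_fraction(gp) * np_ * max(np_ - 1, 1)
                 + _reachable_fraction(ga) * na * max(na - 1, 1)) / (
            np_ * max(np_ - 1, 1) + na * max(na - 1, 1))
    else:
        raise ValueError(f"unknown graph_mode {graph_mode!r}")

    def table(labels, isolated, side):
        tag = "P" if side == "plants" else "A"
        rows = []
        for lab in labels:
            rows.append({"species": lab, "degree": deg[side][lab],
                         "bc": bc[(tag, lab)], "cc": cc[(tag, lab)]})
        for lab in isolated:
            rows.append({"species": lab, "degree": 0, "bc": None, "cc": None})
        return pd.DataFrame(rows).set_index("species")

    plants = table(net.plant_labels, net.isolated_plants, "plants")
    pols = table(net.pollinator_labels, net.isolated_pollinators, "pollinators")
    return CentralityTable(plants, pols, graph_mode, reach)


def keystone_rank(table: CentralityTable, level: str) -> list[str]:
    """Species of a trophic level ordered by composite centrality rank.

    Species are ranked (1 = best, average ranks on ties) separately on
    degree, BC and CC; the ordering key is the mean of the three ranks,
    with ties broken by higher degree and then label. Species with
    undefined centralities (isolated) sort last. The first entry is the
    keystone candidate.
    """
    df = table.level(level)
    if df.empty:
        raise ValueError(f"no species at level {level!r}")
    ranks = df[["degree", "bc", "cc"]].astype(float).rank(
        ascending=False, method="average", na_option="bottom"
    )
    mean_rank = ranks.mean(axis=1)
    order = pd.DataFrame({
        "mean_rank": mean_rank,
        "neg_degree": -df["degree"].astype(float),
        "label": df.index,
    })
    return list(order.sort_values(["mean_rank", "neg_degree", "label"]).index)
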