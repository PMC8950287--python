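"""Centrality scores against hand geodesics and a brute-force all-pairs
shortest-path oracle, plus the composite keystone ranking."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from pollinet import centralities, keystone_rank, network_from_matrix
from pollinet.centrality import CentralityTable

# ---------------------------------------------------------------------------
# brute-force oracle: enumerate all shortest paths explicitly
# ---------------------------------------------------------------------------


def bc_oracle(g: nx.Graph) -> dict:
    n = g.number_of_nodes()
    score = {v: 0.0 for v in g}
    for s, t in itertools.combinations(g.nodes, 2):
        try:
            paths = list(nx.all_shortest_paths(g, s, t))
        except nx.NetworkXNoPath:
            continue
        for v in g:
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p)
            score[v] += through / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return {v: x / norm for v, x in score.items()}


def cc_oracle(g: nx.Graph) -> dict:
    out = {}
    for v in g:
        dists = dict(nx.single_source_shortest_path_length(g, v))
        total = sum(d for u, d in dists.items() if u != v)
        out[v] = 1.0 / total if total else None
    return out


class TestCentralities:
    def test_path_graph_hand_geodesics(self):
        # plant a -- pollinator x -- plant b
        net = network_from_matrix([[1], [1]], ["a", "b"], ["x"])
        tab = centralities(net)
        assert tab.pollinators.loc["x", "bc"] == pytest.approx(1.0)
        assert tab.pollinators.loc["x", "cc"] == pytest.approx(1 / 2)
        assert tab.plants.loc["a", "cc"] == pytest.approx(1 / 3)
        assert tab.plants.loc["b", "cc"] == pytest.approx(1 / 3)
        assert tab.plants.loc["a", "bc"] == 0.0

    def test_star_graph(self):
        net = network_from_matrix([[1], [1], [1], [1]])
        tab = centralities(net)
        assert tab.pollinators.loc["a1", "bc"] == pytest.approx(1.0)
        assert (tab.plants["bc"] == 0).all()

    def test_matches_oracle_on_random_graphs(self, rng):
        checked = 0
        while checked < 100:
            r, a = rng.integers(2, 9, size=2)
            m = (rng.random((r, a)) < 0.4).astype(int)
            if not (m.sum(axis=1).all() and m.sum(axis=0).all()):
                continue
            net = network_from_matrix(m)
            tab = centralities(net)
            g = nx.Graph()
            for i in range(net.n_plants):
                for j in range(net.n_pollinators):
                    if net.weights[i, j]:
                        g.add_edge(("P", net.plant_labels[i]), ("A", net.pollinator_labels[j]))
            bc = bc_oracle(g)
            cc = cc_oracle(g)
            for p in net.plant_labels:
                assert tab.plants.loc[p, "bc"] == pytest.approx(bc[("P", p)], abs=1e-9)
                assert tab.plants.loc[p, "cc"] == pytest.approx(cc[("P", p)], abs=1e-9)
            for q in net.pollinator_labels:
                assert tab.pollinators.loc[q, "bc"] == pytest.approx(bc[("A", q)], abs=1e-9)
            checked += 1

    def test_relabeling_invariance(self):
        m = [[1, 1, 0], [0, 1, 1]]
        t1 = centralities(network_from_matrix(m, ["u", "v"], ["x", "y", "z"]))
        t2 = centralities(network_from_matrix(m, ["p9", "p8"], ["q1", "q2", "q3"]))
        assert np.allclose(t1.plants[["bc", "cc"]].to_numpy(dtype=float),
                           t2.plants[["bc", "cc"]].to_numpy(dtype=float))

    def test_isolated_species_undefined_centralities(self):
        net = network_from_matrix([[1, 0], [0, 0]])
        tab = centralities(net)
        assert tab.plants.loc["p2", "degree"] == 0
        assert pd.isna(tab.plants.loc["p2", "bc"])

    def test_projection_mode_runs_and_differs(self):
        net = network_from_matrix([[1, 1, 0], [0, 1, 1], [1, 0, 1]])
        tb = centralities(net, "bipartite")
        tp = centralities(net, "projection")
        assert tp.graph_mode == "projection"
        assert not np.allclose(tb.plants["cc"].astype(float), tp.plants["cc"].astype(float))

    def test_bc_in_unit_interval(self, rng):
        for _ in range(10):
            m = (rng.random((5, 5)) < 0.5).astype(int)
            if not (m.sum(axis=1).all() and m.sum(axis=0).all()):
                continue
            tab = centralities(network_from_matrix(m))
            assert tab.plants["bc"].astype(float).between(0, 1).all()


def table_from_values(values):
    """CentralityTable with given per-species (degree, bc, cc) dicts."""
    def df(d):
        return pd.DataFrame(
            [{"species": k, "degree": v[0], "bc": v[1], "cc": v[2]} for k, v in d.items()]
        ).set_index("species")

    return CentralityTable(df(values["plant"]), df(values["pollinator"]), "bipartite", 1.0)


# printed per-species scores of the survey (degree, BC, CC)
POLLINATOR_SCORES = {
    "Eucera sp. 1": (1, 0.000, 0.030),
    "Pristomyrmex pungens": (1, 0.000, 0.055),
    "Ceratina flavipes": (1, 0.000, 0.055),
    "Lasioglossum exiliceps": (2, 0.016, 0.057),
    "Lasioglossum virideglaucum": (8, 0.259, 0.070),
    "Lasioglossum duplex": (3, 0.083, 0.062),
    "Lasioglossum miyabei": (2, 0.153, 0.047),
    "Eristalomyia tenax": (1, 0.000, 0.049),
    "Metasyrphus luniger": (5, 0.176, 0.068),
    "Curculionidae sp. 1": (2, 0.016, 0.053),
    "Oedemeridae sp. 1": (3, 0.188, 0.063),
    "Elateridae sp. 1": (1, 0.000, 0.035),
    "Vespidae sp. 1": (1, 0.000, 0.044),
    "Parnassius stubbendorfii": (2, 0.035, 0.061),
    "Bombylius major": (2, 0.024, 0.057),
    "Carterocephalus silvicola": (1, 0.000, 0.049),
    "Andrena sp. 1": (2, 0.005, 0.047),
    "Apis mellifera": (3, 0.044, 0.059),
    "Philopota nigroaenea": (1, 0.000, 0.042),
}

PLANT_SCORES = {
    "Polygonatum odoratum var. pluriflorum": (2, 0.000, 0.059),
    "Ranunculus japonicus": (10, 0.238, 0.106),
    "Viola mandshurica": (0, None, None),
    "Rhododendron schlippenbachii": (5, 0.048, 0.100),
    "Cypripedium guttatum": (1, 0.000, 0.095),
    "Aruncus dioicus var. kamtschaticus": (2, 0.000, 0.065),
    "Weigela florida": (4, 0.000, 0.095),
    "Arabis gemmifera": (5, 0.476, 0.106),
    "Taraxacum officinale": (1, 0.000, 0.078),
    "Barbarea vulgaris": (1, 0.000, 0.095),
    "Valeriana fauriei": (7, 0.238, 0.106),
    "Cerastium holosteoides var. hallaisanensis": (4, 0.000, 0.095),
}


class TestKeystoneRank:
    def test_dominating_species_ranks_first(self):
        tab = table_from_values({
            "plant": {"top": (5, 0.9, 0.5), "mid": (3, 0.2, 0.3), "low": (1, 0.0, 0.1)},
            "pollinator": {"x": (1, 0.0, 0.1)},
        })
        assert keystone_rank(tab, "plant")[0] == "top"

    def test_survey_keystone_pollinator_is_sweat_bee(self):
        tab = table_from_values({"plant": PLANT_SCORES, "pollinator": POLLINATOR_SCORES})
        assert keystone_rank(tab, "pollinator")[0] == "Lasioglossum virideglaucum"

    def test_survey_keystone_plant_has_top_betweenness(self):
        tab = table_from_values({"plant": PLANT_SCORES, "pollinator": POLLINATOR_SCORES})
        best_bc = max((v[1] or 0) for v in PLANT_SCORES.values())
        assert PLANT_SCORES["Arabis gemmifera"][1] == best_bc == 0.476
        assert keystone_rank(tab, "plant")[0] in ("Arabis gemmifera", "Ranunculus japonicus")

    def test_rank_is_stable_and_pure(self):
        tab = table_from_values({"plant": PLANT_SCORES, "pollinator": POLLINATOR_SCORES})
        first = keystone_rank(tab, "pollinator")
        assert keystone_rank(tab, "pollinator") == first
        assert set(first) == set(POLLINATOR_SCORES)

    def test_isolated_species_sorts_last(self):
        tab = table_from_values({"plant": PLANT_SCORES, "pollinator": POLLINATOR_SCORES})
        assert keystone_rank(tab, "plant")[-1] == "Viola mandshurica"

    def test_empty_level_rejected(self):
        tab = table_from_values({"plant": PLANT_SCORES, "pollinator": POLLINATOR_SCORES})
        with pytest.raises(ValueError):
            keystone_rank(tab, "fungus")
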