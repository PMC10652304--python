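"""Network centrality, calibration, and community detection."""

import itertools

import networkx as nx
import numpy as np
import pytest

from redoxsens.network import (
    calibrated_subnetwork,
    community_centrality_profile,
    eigenvector_centrality,
    load_network,
    louvain_partition,
    membership_upset,
    write_network,
)


def _two_cliques():
    g = nx.disjoint_union(nx.complete_graph(4), nx.complete_graph(4))
    g.add_edge(0, 4)
    return nx.relabel_nodes(g, str)


def test_load_network_merges_and_thresholds(tmp_path):
    path = tmp_path / "edges.tsv"
    path.write_text(
        "protein1\tprotein2\tcombined_score\n"
        "a\tb\t700\n"
        "b\ta\t650\n"  # duplicate orientation, keep max
        "a\ta\t900\n"  # self-loop dropped
        "c\td\t150\n"  # below threshold
    )
    g = load_network(path, min_score=400)
    assert g.number_of_edges() == 1
    assert g["a"]["b"]["score"] == 700


def test_load_network_errors_and_empty(tmp_path):
    bad = tmp_path / "bad.tsv"
    bad.write_text("a\tb\n")
    with pytest.raises(ValueError, match=":1"):
        load_network(bad)
    empty = tmp_path / "empty.tsv"
    empty.write_text("")
    with pytest.warns(UserWarning):
        g = load_network(empty)
    assert g.number_of_nodes() == 0


def test_network_round_trip(tmp_path):
    g = _two_cliques()
    for a, b in g.edges():
        g[a][b]["score"] = 800
    path = tmp_path / "net.tsv"
    write_network(g, path)
    g2 = load_network(path)
    assert set(map(frozenset, g.edges())) == set(map(frozenset, g2.edges()))


def test_star_graph_centrality_closed_form():
    g = nx.relabel_nodes(nx.star_graph(3), str)
    cmap = eigenvector_centrality(g)
    assert cmap["0"] == pytest.approx(1 / np.sqrt(2), abs=1e-8)
    for leaf in "123":
        assert cmap[leaf] == pytest.approx(1 / np.sqrt(6), abs=1e-8)
    vec = np.array(list(cmap.values.values()))
    assert np.linalg.norm(vec) == pytest.approx(1.0, abs=1e-12)
    assert (vec >= 0).all()


def test_complete_graph_centrality_symmetry():
    cmap = eigenvector_centrality(nx.relabel_nodes(nx.complete_graph(4), str))
    assert all(v == pytest.approx(0.5, abs=1e-10) for v in cmap.values.values())


def test_centrality_matches_independent_implementation():
    g = nx.relabel_nodes(nx.gnp_random_graph(60, 0.1, seed=5), str)
    g = g.subgraph(max(nx.connected_components(g), key=len)).copy()
    mine = eigenvector_centrality(g)
    ref = nx.eigenvector_centrality_numpy(g)
    for node, value in mine.values.items():
        assert value == pytest.approx(abs(ref[node]), abs=1e-6)


def test_centrality_relabeling_invariance():
    g = nx.relabel_nodes(nx.gnp_random_graph(30, 0.2, seed=1), str)
    relabeled = nx.relabel_nodes(g, {n: f"x{n}" for n in g})
    a = eigenvector_centrality(g)
    b = eigenvector_centrality(relabeled)
    for node in g:
        assert a[node] == pytest.approx(b[f"x{node}"], abs=1e-12)


def test_centrality_guards():
    with pytest.raises(ValueError):
        eigenvector_centrality(nx.Graph())
    g = nx.relabel_nodes(nx.path_graph(50), str)
    with pytest.raises(RuntimeError, match="max_iter"):
        eigenvector_centrality(g, tol=1e-15, max_iter=2)


def test_calibrated_subnetwork_identity():
    g = nx.relabel_nodes(nx.gnp_random_graph(40, 0.15, seed=2), str)
    cmap = eigenvector_centrality(g)
    detected = [str(i) for i in range(0, 40, 2)]
    sub, sub_cmap = calibrated_subnetwork(g, cmap, detected)
    assert set(sub.nodes()) == set(detected)
    for pid in detected:
        assert sub_cmap[pid] == cmap[pid]  # exact equality, no recomputation
    assert sub_cmap.scope == "subnetwork-calibrated"

    full_sub, full_cmap = calibrated_subnetwork(g, cmap, list(g.nodes()))
    assert full_sub.number_of_edges() == g.number_of_edges()

    with pytest.warns(UserWarning):
        calibrated_subnetwork(g, cmap, ["0", "ghost"])
    with pytest.raises(ValueError), pytest.warns(UserWarning):
        calibrated_subnetwork(g, cmap, ["ghost"])


def _exhaustive_best_partition(g):
    """Brute-force modularity maximum over all partitions (tiny graphs)."""
    nodes = list(g.nodes())

    def partitions(seq):
        if not seq:
            yield []
            return
        head, rest = seq[0], seq[1:]
        for part in partitions(rest):
            for i in range(len(part)):
                yield part[:i] + [part[i] | {head}] + part[i + 1:]
            yield part + [{head}]

    best, best_q = None, -np.inf
    for part in partitions(nodes):
        q = nx.community.modularity(g, part)
        if q > best_q:
            best, best_q = part, q
    return best, best_q


def test_louvain_matches_exhaustive_optimum_on_two_cliques():
    g = _two_cliques()
    part = louvain_partition(g, seed=0)
    found = {frozenset(c) for c in part.communities().values()}
    best, best_q = _exhaustive_best_partition(g)
    assert found == {frozenset(c) for c in best}
    assert part.modularity == pytest.approx(best_q)
    # the optimum is exactly the two cliques
    assert found == {frozenset("0123"), frozenset("4567")}


def test_louvain_complete_graph_single_community():
    part = louvain_partition(nx.relabel_nodes(nx.complete_graph(6), str), seed=0)
    assert len(set(part.labels.values())) == 1


def test_louvain_contracts():
    g = _two_cliques()
    a = louvain_partition(g, seed=3)
    b = louvain_partition(g, seed=3)
    assert a.labels == b.labels  # deterministic under fixed seed
    singleton_q = nx.community.modularity(g, [{n} for n in g])
    assert a.modularity >= singleton_q
    with pytest.raises(ValueError):
        louvain_partition(nx.empty_graph(3, create_using=nx.Graph))


def test_louvain_partitions_largest_component_only():
    g = _two_cliques()
    g.add_node("isolated")
    part = louvain_partition(g, seed=0)
    assert "isolated" not in part.labels
    assert set(part.labels) == set("01234567")


def test_community_centrality_profile():
    g = _two_cliques()
    hub_graph = g.copy()
    for leaf in ("h1", "h2", "h3", "h4", "h5"):
        hub_graph.add_edge("0", leaf)  # make node 0 a hub in community A
    cmap = eigenvector_centrality(hub_graph)
    part = louvain_partition(g, seed=0)
    profile = community_centrality_profile(part, cmap)
    label_of_0 = part.labels["0"]
    assert profile.loc[label_of_0, "max"] == max(
        profile["max"]
    )  # hub's community holds the global max
    assert profile["count"].sum() == 8

    single = louvain_partition(nx.relabel_nodes(nx.complete_graph(5), str), seed=0)
    single_profile = community_centrality_profile(
        single, eigenvector_centrality(nx.relabel_nodes(nx.complete_graph(5), str))
    )
    assert single_profile.shape[0] == 1 and single_profile["count"].iloc[0] == 5


def test_membership_upset_counts(top20):
    partition = dict(zip(top20["gene_name"], top20["community"]))
    old = dict(zip(top20["gene_name"], top20["old_sign"]))
    young = dict(zip(top20["gene_name"], top20["young_sign"]))
    counts = membership_upset(partition, old, young)
    # independent count straight off the fixture
    expected = int(
        ((top20["community"] == "Metabolic stress response") & (top20["old_sign"] == -1)).sum()
    )
    row = counts[
        (counts["community"] == "Metabolic stress response")
        & (counts["age"] == "old")
        & (counts["sign"] == -1)
    ]
    assert int(row["count"].iloc[0]) == expected == 4
    # combination counts partition the signed (protein, age) observations
    signed = int((top20["old_sign"] != 0).sum() + (top20["young_sign"] != 0).sum())
    assert counts["count"].sum() == signed


def test_membership_upset_all_zero_signs():
    partition = {"a": 0, "b": 0}
    counts = membership_upset(partition, {"a": 0, "b": 0}, {"a": 0, "b": 0})
    assert counts.empty
    assert counts.attrs["no_change"] == 4
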