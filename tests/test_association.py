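"""Association networks: robustness protocol, clusters, network statistics."""

import numpy as np
import pandas as pd
import pytest
import networkx as nx

from aquadyn.association import (AssociationNetwork, AssociationParams,
                                 ClusterAssignment, cluster_timeseries,
                                 cluster_unifrac_test, extract_clusters,
                                 filter_core_otus, network_stats,
                                 robust_associations)
from aquadyn.table import OtuTable, SampleMetadata


def _net_from_edges(edges, nodes=()):
    g = nx.Graph()
    g.add_nodes_from(nodes)
    for a, b, sign in edges:
        g.add_edge(a, b, sign=sign, mic=0.5, discoveries=10)
    return AssociationNetwork(g, sorted(g.nodes), 100, AssociationParams())


# ---------------------------------------------------------------------------
# robust protocol on generator data
# ---------------------------------------------------------------------------

def test_planted_clusters_sign_structure(seasonal_data, seasonal_network):
    """Within-cluster edges are all positive and cross-cluster edges all
    negative, mirroring the anti-phase seasonal construction."""
    net, _ = seasonal_network
    t1 = set(seasonal_data.truth.cluster_members[1])
    t2 = set(seasonal_data.truth.cluster_members[2])
    assert net.graph.number_of_edges() > 30
    for a, b, d in net.graph.edges(data=True):
        assert (a in t1 | t2) and (b in t1 | t2)  # no spurious bystander edges
        if (a in t1) == (b in t1):
            assert d["sign"] > 0
        else:
            assert d["sign"] < 0


def test_network_invariant_to_column_and_event_order(seasonal_events):
    params = AssociationParams(seed=0, n_null=100)
    events = seasonal_events[:6]
    core = filter_core_otus(events, 0.30)
    ref = robust_associations(events, params, core_otus=core)

    rng = np.random.default_rng(1)
    shuffled_cols = list(rng.permutation(events[0].otu_ids))
    events_shuf = [ev.select_otus(shuffled_cols) for ev in events[::-1]]
    alt = robust_associations(events_shuf, params,
                              core_otus=list(rng.permutation(core)))
    ref_edges = {tuple(sorted(e)): d["sign"] for *e, d in ref.graph.edges(data=True)}
    alt_edges = {tuple(sorted(e)): d["sign"] for *e, d in alt.graph.edges(data=True)}
    assert ref_edges == alt_edges


def test_null_tables_give_no_edges():
    """I.i.d. OTU profiles produce (essentially) no robust associations."""
    rng = np.random.default_rng(5)
    events = []
    for e in range(10):
        counts = rng.poisson(30, size=(40, 12)) + 1
        events.append(OtuTable([f"s{i}" for i in range(40)],
                               [f"o{j}" for j in range(12)], counts))
    net = robust_associations(events, AssociationParams(
        seed=0, n_null=150, min_points=10, min_discoveries=3))
    assert net.graph.number_of_edges() == 0


def test_empty_filter_warns():
    t = OtuTable(["s1", "s2"], ["a", "b"], np.array([[1, 0], [0, 1]]))
    with pytest.warns(UserWarning, match="fewer than two"):
        net = robust_associations([t], AssociationParams(min_detection=0.99))
    assert net.graph.number_of_edges() == 0


# ---------------------------------------------------------------------------
# cluster extraction on toy graphs
# ---------------------------------------------------------------------------

def test_two_positive_cliques_with_negative_bridge():
    edges = [("a1", "a2", 1), ("a2", "a3", 1), ("a1", "a3", 1),
             ("b1", "b2", 1), ("b2", "b3", 1), ("b1", "b3", 1),
             ("a1", "b1", -1), ("a2", "b2", -1)]
    asg = extract_clusters(_net_from_edges(edges, nodes=["iso1"]))
    assert asg.labels["a1"] == asg.labels["a2"] == asg.labels["a3"]
    assert asg.labels["b1"] == asg.labels["b2"] == asg.labels["b3"]
    assert asg.labels["a1"] != asg.labels["b1"]
    assert asg.labels["iso1"] == "isolated"
    assert asg.within_cluster_negative_edges == []
    # cluster 1 is the larger or lexicographically first component
    assert set(asg.cluster_labels()) == {1, 2}


def test_bridge_node_spanning_cliques_is_unassigned():
    edges = [("a1", "a2", 1), ("a2", "a3", 1), ("a1", "a3", 1),
             ("b1", "b2", 1), ("b2", "b3", 1), ("b1", "b3", 1),
             ("x", "a1", 1), ("x", "b1", 1)]
    asg = extract_clusters(_net_from_edges(edges))
    assert asg.labels["x"] == "unassigned"
    assert asg.labels["a1"] != asg.labels["b1"]


def test_only_negative_edges_is_unassigned():
    edges = [("a1", "a2", 1), ("n1", "a1", -1)]
    asg = extract_clusters(_net_from_edges(edges))
    assert asg.labels["n1"] == "unassigned"


def test_within_cluster_negative_edge_reported():
    edges = [("a1", "a2", 1), ("a2", "a3", 1), ("a1", "a3", -1)]
    asg = extract_clusters(_net_from_edges(edges))
    assert asg.within_cluster_negative_edges == [("a1", "a3")]


# ---------------------------------------------------------------------------
# network statistics
# ---------------------------------------------------------------------------

def test_triangle_stats():
    stats = network_stats(_net_from_edges([("a", "b", 1), ("b", "c", 1),
                                           ("a", "c", 1)]))
    assert stats["density"] == pytest.approx(1.0)
    assert stats["clustering_coefficient"] == pytest.approx(1.0)


def test_star_clustering_zero():
    stats = network_stats(_net_from_edges([("h", "x", 1), ("h", "y", 1),
                                           ("h", "z", 1)]))
    assert stats["clustering_coefficient"] == 0.0
    assert stats["density"] == pytest.approx(3 / 6)


def test_five_node_hand_counted():
    """Graph: square a-b-c-d-a plus diagonal a-c and pendant e on a.

    Hand count: triangles abc and acd.  Local coefficients:
    a: deg 4 (b,c,d,e), pairs 6, links among neighbors b-c, c-d -> 2/6;
    b: deg 2, neighbors a,c linked -> 1; c: deg 3 (b,a,d), links a-b,
    a-d -> 2/3; d: deg 2 -> 1; e: deg 1 -> 0.
    Mean = (1/3 + 1 + 2/3 + 1 + 0)/5 = 0.6; density 6/10.
    """
    edges = [("a", "b", 1), ("b", "c", 1), ("c", "d", 1), ("d", "a", 1),
             ("a", "c", -1), ("a", "e", 1)]
    stats = network_stats(_net_from_edges(edges))
    assert stats["n_edges"] == 6
    assert stats["density"] == pytest.approx(6 / 10)
    assert stats["clustering_coefficient"] == pytest.approx(0.6)


def test_cluster_density(seasonal_network):
    net, asg = seasonal_network
    stats = network_stats(net, asg)
    for label, dens in stats["cluster_density"].items():
        members = asg.members(label)
        k = len(members)
        e = net.graph.subgraph(members).number_of_edges()
        assert dens == pytest.approx(e / (k * (k - 1) / 2))
        assert 0 < dens <= 1


# ---------------------------------------------------------------------------
# cluster time series
# ---------------------------------------------------------------------------

def _mini_meta(samples, months):
    return SampleMetadata(pd.DataFrame({
        "location": ["L1"] * len(samples), "sector": ["S1"] * len(samples),
        "month_index": months,
        "calendar_month": [f"2010-{m + 6:02d}" for m in months],
    }, index=samples))


def test_cluster_timeseries_sums_to_subset_total():
    counts = np.array([[10, 10, 30, 50], [20, 20, 30, 30]])
    t = OtuTable(["s1", "s2"], ["a", "b", "c", "d"], counts)
    asg = ClusterAssignment({"a": 1, "b": 1, "c": 2, "d": "isolated"})
    ts = cluster_timeseries(t, _mini_meta(["s1", "s2"], [0, 1]), asg)
    assert ts.loc[0, 1] == pytest.approx(0.2)
    assert ts.loc[0, 2] == pytest.approx(0.3)
    assert ts.loc[1, "isolated"] == pytest.approx(0.3)
    assert np.allclose(ts.sum(axis=1), 1.0)  # all four OTUs covered here


def test_planted_cluster_series_cross(seasonal_data, seasonal_events,
                                      seasonal_network):
    """Winter and summer cluster abundance series trade dominance: each
    cluster leads in its own season."""
    _, asg = seasonal_network
    data = seasonal_data
    truth = data.truth.cluster_members
    # map extracted labels onto truth clusters by majority membership
    by_label = {}
    for label in asg.cluster_labels():
        members = set(asg.members(label))
        by_label[label] = 1 if len(members & set(truth[1])) >= len(
            members & set(truth[2])) else 2
    ts = cluster_timeseries(data.table, data.metadata, asg)
    cal = {t: int(m.split("-")[1])
           for t, m in zip(data.metadata.frame["month_index"],
                           data.metadata.frame["calendar_month"])}
    winter_label = [l for l, c in by_label.items() if c == 1][0]
    summer_label = [l for l, c in by_label.items() if c == 2][0]
    winter_months = [t for t, c in cal.items() if c in (12, 1, 2)]
    summer_months = [t for t, c in cal.items() if c in (6, 7, 8)]
    assert (ts.loc[winter_months, winter_label].mean()
            > ts.loc[winter_months, summer_label].mean())
    assert (ts.loc[summer_months, summer_label].mean()
            > ts.loc[summer_months, winter_label].mean())


# ---------------------------------------------------------------------------
# phylogenetic separation of clusters
# ---------------------------------------------------------------------------

def test_cluster_unifrac_disjoint_subtrees():
    from skbio import TreeNode

    tree = TreeNode.read(["((a1:1,a2:1):2,(b1:1,b2:1):2);"])
    asg = ClusterAssignment({"a1": 1, "a2": 1, "b1": 2, "b2": 2})
    score, p = cluster_unifrac_test(asg, tree, n_perm=50, seed=0)
    assert score == pytest.approx(1.0)
    assert p < 0.5


def test_cluster_unifrac_permutation_matches_exhaustive():
    """On a 6-leaf tree the permutation p converges to the exact value
    from enumerating all 3-vs-3 splits."""
    import itertools

    from skbio import TreeNode
    from skbio.diversity.beta import unweighted_unifrac

    tree = TreeNode.read(
        ["(((a1:1,a2:1):1,a3:1):1,((b1:1,b2:1):1,b3:1):1);"])
    members_a = ["a1", "a2", "a3"]
    members_b = ["b1", "b2", "b3"]
    asg = ClusterAssignment({**{m: 1 for m in members_a},
                             **{m: 2 for m in members_b}})
    union = members_a + members_b

    def score(a_set):
        u = np.array([1 if o in a_set else 0 for o in union])
        return float(unweighted_unifrac(u, 1 - u, taxa=union, tree=tree))

    obs = score(set(members_a))
    splits = [set(c) for c in itertools.combinations(union, 3)]
    exact = np.mean([score(s) >= obs - 1e-12 for s in splits])
    got, p = cluster_unifrac_test(asg, tree, n_perm=999, seed=1)
    assert got == pytest.approx(obs)
    assert p == pytest.approx(exact, abs=0.05)


def test_cluster_unifrac_empty_cluster_rejected():
    from skbio import TreeNode

    tree = TreeNode.read(["((a:1,b:1):1,c:1);"])
    with pytest.raises(ValueError, match="non-empty"):
        cluster_unifrac_test(ClusterAssignment({"a": 1}), tree)
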