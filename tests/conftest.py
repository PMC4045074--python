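"""Shared fixtures: worked miniature data, synthetic campaigns, toy trees.

The seasonal campaign and its association network are expensive
(minutes) and session-scoped; several tests examine different facets of
the same run.
"""

from __future__ import annotations

import numpy as np
import pytest

from aquadyn.association import (AssociationParams, extract_clusters,
                                 filter_core_otus, robust_associations)
from aquadyn.rarefaction import RarefactionPlan, rarefy
from aquadyn.synthetic import ClusterConfig, SyntheticSpec, generate, worked_fixture


@pytest.fixture()
def worked():
    return worked_fixture()


@pytest.fixture()
def three_leaf_tree():
    from skbio import TreeNode

    # ((A:1, B:2):0.5, C:3);  total branch length 6.5
    return TreeNode.read(["((A:1,B:2):0.5,C:3);"])


@pytest.fixture(scope="session")
def seasonal_data():
    """Scaled-down campaign with the two planted anti-phase clusters."""
    return generate(SyntheticSpec(n_otus=400, seed=11))


@pytest.fixture(scope="session")
def seasonal_events(seasonal_data):
    table = seasonal_data.table
    depth = int(table.sample_totals().min())
    return list(rarefy(table, RarefactionPlan(depth, 20, base_seed=5)))


@pytest.fixture(scope="session")
def seasonal_network(seasonal_events):
    core = filter_core_otus(seasonal_events, 0.30)
    net = robust_associations(seasonal_events,
                              AssociationParams(seed=0, n_null=300),
                              core_otus=core)
    return net, extract_clusters(net)


@pytest.fixture(scope="session")
def null_data():
    """No seasonality, no spatial decay, no site-specific OTUs."""
    spec = SyntheticSpec(n_otus=300, seed=23, spatial_decay=0.0,
                         unique_fraction=0.0,
                         clusters=ClusterConfig(sizes=(), share=0.0))
    return generate(spec)


@pytest.fixture(scope="session")
def null_events(null_data):
    table = null_data.table
    depth = int(table.sample_totals().min())
    return list(rarefy(table, RarefactionPlan(depth, 15, base_seed=9)))


def rand_index(labels_a, labels_b) -> float:
    """Plain Rand index between two labelings of the same items."""
    a = np.asarray(labels_a)
    b = np.asarray(labels_b)
    n = len(a)
    agree = 0
    for i in range(n):
        for j in range(i + 1, n):
            agree += (a[i] == a[j]) == (b[i] == b[j])
    return agree / (n * (n - 1) / 2)
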