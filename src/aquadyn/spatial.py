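"""Pipe-network geometry and distance decay of community structure.

A distribution system is modelled as an undirected graph of pipe
sections, each carrying length (m), wetted surface area (pi * diameter *
length, m^2), age at a reference date (years) and material.  Between two
sampling locations the "water path" is the length-minimizing path; its
summed metrics (total length, total surface, age-weighted length
Sum(L_e * age_e) and age-weighted surface Sum(S_e * age_e)) serve as the
spatial predictors that community dissimilarity is regressed against.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats as sps

from .distances import DistanceMatrix
from .table import OtuTable

__all__ = [
    "PipeInventory", "PipeNetwork", "PathMetrics",
    "shortest_water_path", "distance_decay", "location_average_distance",
    "site_specific_otus",
]

PATH_METRIC_NAMES = ("total_length", "total_surface",
                     "age_weighted_length", "age_weighted_surface")


@dataclass
class PipeInventory:
    """Validated table of pipe sections (meters / calendar years)."""

    sections: pd.DataFrame

    def __post_init__(self) -> None:
        s = self.sections
        if s["section_id"].duplicated().any():
            dup = s["section_id"][s["section_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate section id {dup!r}")
        if (s["length_m"] <= 0).any() or (s["diameter_m"] <= 0).any():
            raise ValueError("pipe lengths and diameters must be positive")

    @property
    def total_length(self) -> float:
        return float(self.sections["length_m"].sum())

    @property
    def total_surface(self) -> float:
        s = self.sections
        return float((math.pi * s["diameter_m"] * s["length_m"]).sum())

    def check_connectivity(self, sampling_nodes, dwtp_node: str = "DWTP") -> None:
        g = nx.Graph()
        for _, row in self.sections.iterrows():
            g.add_edge(row["node_a"], row["node_b"])
        missing = [n for n in [dwtp_node, *sampling_nodes] if n not in g]
        if missing:
            raise ValueError(f"nodes absent from inventory: {missing}")
        reachable = nx.node_connected_component(g, dwtp_node)
        unreachable = [n for n in sampling_nodes if n not in reachable]
        if unreachable:
            raise ValueError(
                f"sampling nodes not connected to {dwtp_node}: {unreachable}")


class PipeNetwork:
    """Graph view of an inventory with per-edge derived metrics."""

    def __init__(self, inventory: PipeInventory, reference_year: float):
        self.inventory = inventory
        self.reference_year = reference_year
        g = nx.Graph()
        for _, row in inventory.sections.iterrows():
            length = float(row["length_m"])
            surface = math.pi * float(row["diameter_m"]) * length
            age = max(reference_year - float(row["install_year"]), 0.0)
            g.add_edge(row["node_a"], row["node_b"], length=length,
                       surface=surface, age=age, material=row["material"],
                       section_id=row["section_id"])
        if not nx.is_connected(g):
            parts = [sorted(c)[:3] for c in nx.connected_components(g)]
            raise ValueError(f"pipe network is disconnected: components {parts}")
        self.graph = g


@dataclass
class PathMetrics:
    total_length: float
    total_surface: float
    age_weighted_length: float
    age_weighted_surface: float

    def as_dict(self) -> dict[str, float]:
        return {k: getattr(self, k) for k in PATH_METRIC_NAMES}

    def __add__(self, other: "PathMetrics") -> "PathMetrics":
        return PathMetrics(*(getattr(self, k) + getattr(other, k)
                             for k in PATH_METRIC_NAMES))


def shortest_water_path(net: PipeNetwork, a: str, b: str) -> PathMetrics:
    """Metrics summed along the length-minimizing path between two nodes.

    Ties on total length are broken by smaller total surface, then by
    lexicographic node sequence, so the result is deterministic.
    """
    g = net.graph
    if a not in g or b not in g:
        missing = [n for n in (a, b) if n not in g]
        raise KeyError(f"nodes not in network: {missing}")
    if a == b:
        return PathMetrics(0.0, 0.0, 0.0, 0.0)
    try:
        best_len = nx.shortest_path_length(g, a, b, weight="length")
    except nx.NetworkXNoPath as exc:
        raise ValueError(f"no path between {a!r} and {b!r}") from exc
    candidates = []
    for path in nx.all_shortest_paths(g, a, b, weight="length"):
        surf = sum(g[u][v]["surface"] for u, v in itertools.pairwise(path))
        candidates.append((surf, tuple(path)))
    _, path = min(candidates)
    tl = ts = awl = aws = 0.0
    for u, v in itertools.pairwise(path):
        e = g[u][v]
        tl += e["length"]
        ts += e["surface"]
        awl += e["length"] * e["age"]
        aws += e["surface"] * e["age"]
    assert abs(tl - best_len) < 1e-6 * max(best_len, 1.0)
    return PathMetrics(tl, ts, awl, aws)


def location_average_distance(dm: DistanceMatrix, locations,
                              months=None) -> DistanceMatrix:
    """Collapse a sample-level matrix to mean between-location distance.

    When ``months`` is given (one label per sample), only pairs sampled
    in the same month are averaged -- the campaign-average spatial
    contrast, with the temporal signal held fixed.  Otherwise all cross
    pairs enter the mean.
    """
    lab = np.asarray(list(locations))
    if len(lab) != len(dm):
        raise ValueError("one location per sample required")
    mon = None if months is None else np.asarray(list(months))
    locs = sorted(set(lab))
    data = np.zeros((len(locs), len(locs)))
    for i, a in enumerate(locs):
        for j in range(i + 1, len(locs)):
            ia = np.flatnonzero(lab == a)
            ib = np.flatnonzero(lab == locs[j])
            if mon is not None:
                vals = [dm.data[x, y] for x in ia for y in ib
                        if mon[x] == mon[y]]
            else:
                vals = dm.data[np.ix_(ia, ib)].ravel()
            if len(vals) == 0:
                raise ValueError(f"no comparable pairs for ({a}, {locs[j]})")
            data[i, j] = data[j, i] = float(np.mean(vals))
    return DistanceMatrix(locs, data, dm.metric)


def distance_decay(net: PipeNetwork, dm: DistanceMatrix,
                   locations) -> pd.DataFrame:
    """Pearson correlation of pipe-path metrics with community dissimilarity.

    ``dm`` is a location-level (e.g. time-averaged) dissimilarity matrix;
    all unordered pairs among ``locations`` are used.  Returns one row
    per path-metric component with r, p and the number of pairs.
    """
    locations = list(locations)
    pairs = list(itertools.combinations(locations, 2))
    if len(pairs) < 3:
        raise ValueError("need at least 3 location pairs for a correlation")
    dissim = np.array([dm.between(a, b) for a, b in pairs])
    metrics = {name: [] for name in PATH_METRIC_NAMES}
    for a, b in pairs:
        pm = shortest_water_path(net, a, b)
        for name in PATH_METRIC_NAMES:
            metrics[name].append(getattr(pm, name))
    rows = []
    for name in PATH_METRIC_NAMES:
        x = np.asarray(metrics[name])
        if np.std(x) == 0 or np.std(dissim) == 0:
            rows.append((name, math.nan, math.nan, len(pairs)))
            continue
        r, p = sps.pearsonr(x, dissim)
        rows.append((name, float(r), float(p), len(pairs)))
    return pd.DataFrame(rows, columns=["metric", "pearson_r", "p_value", "n_pairs"])


def site_specific_otus(table: OtuTable, sample_locations) -> pd.DataFrame:
    """Per-location fraction of membership and abundance that is site-specific.

    Counts are pooled over the whole campaign per location; an OTU is
    location-specific when its pooled count is nonzero at exactly one
    location.  Fractions are over each location's detected membership
    and pooled reads.
    """
    locs = np.asarray(list(sample_locations))
    if len(locs) != table.n_samples:
        raise ValueError("one location per sample required")
    uniq = pd.unique(locs)
    if len(uniq) < 2:
        raise ValueError("need at least 2 locations")
    pooled = np.vstack([table.counts[locs == l].sum(axis=0) for l in uniq])
    detected = pooled > 0
    n_locs_detected = detected.sum(axis=0)
    rows = []
    for i, l in enumerate(uniq):
        det = detected[i]
        unique_here = det & (n_locs_detected == 1)
        membership = det.sum()
        reads = pooled[i].sum()
        rows.append((l, int(unique_here.sum()), int(membership),
                     unique_here.sum() / membership if membership else 0.0,
                     pooled[i][unique_here].sum() / reads if reads else 0.0))
    return pd.DataFrame(rows, columns=["location", "n_unique", "n_detected",
                                       "membership_fraction_unique",
                                       "abundance_fraction_unique"])
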