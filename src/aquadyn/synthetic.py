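"""Synthetic monitoring campaigns with full ground-truth bookkeeping.

The generator emulates the processed artifacts of a monthly
drinking-water survey: an OTU count table over (months x locations)
samples, sample metadata with seasonally varying water chemistry, a
rooted phylogeny, and a pipe inventory connecting the sampling
locations to the treatment plant.  Planted structure:

* a lognormal baseline abundance distribution;
* two anti-phase seasonal OTU clusters (12-month sinusoids on the log
  scale, one peaking in winter and one in summer);
* spatially accumulating community drift via biofilm seeding: every
  pipe link hosts a fixed "biofilm" community that bleeds into the
  passing water in proportion to the link's length, so the unshared
  blend mass -- and with it the expected dissimilarity -- between two
  locations grows linearly with the pipe length of the water path
  between them (a planted distance decay that is weak in magnitude yet
  cleanly ordered, as in real systems);
* location-specific OTUs (a reserved slice of the OTU pool per
  location);
* an occupancy law: per OTU and month, presence is thinned so that the
  realized (mean abundance, detection frequency) pairs follow a chosen
  occupancy-abundance model at a chosen alpha.  The retention
  probability r solves  r * P_detect = P_model(alpha, r * mu)  per
  OTU-month (bisection), accounting for the fact that thinning lowers
  the realized mean abundance as well as the detection frequency.

Counts are multinomial draws at lognormally distributed per-sample
depths.  Identical spec + seed reproduce byte-identical outputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .ioam import predict
from .spatial import PipeInventory
from .table import OtuTable, SampleMetadata

__all__ = ["ClusterConfig", "SyntheticSpec", "GroundTruth", "GeneratedData",
           "generate", "worked_fixture"]

_MATERIALS = ("cast iron", "ductile iron", "PVC", "concrete", "copper")

# location-level layout: sector 1 is a linear chain, sectors 2 and 3 branch
# (lengths in meters, before scaling to the requested network total)
_LAYOUT = [
    ("DWTP", "S1.1", 2000.0), ("S1.1", "S1.2", 3000.0), ("S1.2", "S1.3", 4000.0),
    ("DWTP", "J2", 1500.0), ("J2", "S2.1", 2500.0),
    ("J2", "S2.2", 2000.0), ("S2.2", "S2.3", 3000.0),
    ("DWTP", "J3", 2500.0), ("J3", "S3.1", 3000.0),
    ("J3", "S3.2", 4000.0), ("J3", "S3.3", 3500.0),
]
_LOCATIONS = ("DWTP", "S1.1", "S1.2", "S1.3", "S2.1", "S2.2", "S2.3",
              "S3.1", "S3.2", "S3.3")


@dataclass(frozen=True)
class ClusterConfig:
    sizes: tuple[int, ...] = (24, 32)
    amplitude: float = 1.2          # log-scale sinusoid amplitude
    period_months: float = 12.0
    peak_calendar_months: tuple[int, ...] = (12, 6)  # cluster 1 winter, 2 summer
    share: float = 0.55             # community fraction held by cluster members
    member_sdlog: float = 1.0       # abundance spread within the clusters


@dataclass(frozen=True)
class SyntheticSpec:
    n_otus: int = 4369
    n_months: int = 15
    start_month: str = "2010-06"
    abundance_meanlog: float = 0.0
    abundance_sdlog: float = 2.5
    sample_noise_sd: float = 0.3    # per-sample lognormal noise on expectations
    clusters: ClusterConfig = field(default_factory=ClusterConfig)
    occupancy_model: str = "hanski_gyllenberg"
    occupancy_alpha: float = 896.0
    spatial_decay: float = 0.006    # log-sd accumulated per sqrt(meter) of pipe
    unique_fraction: float = 0.15   # share of the OTU pool reserved as site-specific
    depth_meanlog: float = 7.8      # per-sample sequencing depth, lognormal
    depth_sdlog: float = 0.6
    depth_min: int = 834
    depth_max: int = 16817
    n_pipe_sections: int = 881
    total_pipe_km: float = 46.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.clusters, dict):  # e.g. deserialized from YAML
            object.__setattr__(self, "clusters", ClusterConfig(**self.clusters))
        if not isinstance(self.clusters.sizes, tuple):
            object.__setattr__(self, "clusters",
                               ClusterConfig(tuple(self.clusters.sizes),
                                             self.clusters.amplitude,
                                             self.clusters.period_months,
                                             tuple(self.clusters.peak_calendar_months)))
        if sum(self.clusters.sizes) > self.n_otus:
            raise ValueError("cluster sizes exceed the OTU pool")
        if not 0 <= self.unique_fraction < 1:
            raise ValueError("unique_fraction must be in [0, 1)")
        n_unique = int(self.unique_fraction * self.n_otus)
        if sum(self.clusters.sizes) + n_unique > self.n_otus:
            raise ValueError("clusters plus unique OTUs exceed the OTU pool")


@dataclass
class GroundTruth:
    cluster_members: dict[int, list[str]]
    occupancy_model: str
    occupancy_alpha: float
    spatial_decay: float
    unique_otus: dict[str, list[str]]
    pipe_total_length_m: float
    pipe_total_surface_m2: float
    n_pipe_sections: int
    path_length_from_dwtp: dict[str, float]
    depths: dict[str, int]


@dataclass
class GeneratedData:
    table: OtuTable
    metadata: SampleMetadata
    tree: object                 # skbio TreeNode
    inventory: PipeInventory
    truth: GroundTruth


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _calendar_months(start: str, n: int) -> list[str]:
    y, m = (int(v) for v in start.split("-"))
    out = []
    for _ in range(n):
        out.append(f"{y:04d}-{m:02d}")
        m += 1
        if m == 13:
            y, m = y + 1, 1
    return out


def _build_inventory(spec: SyntheticSpec, rng) -> tuple[PipeInventory, dict[str, float]]:
    scale = spec.total_pipe_km * 1000.0 / sum(l for _, _, l in _LAYOUT)
    links = [(a, b, l * scale) for a, b, l in _LAYOUT]
    # distribute sections over links proportionally to length
    total = sum(l for _, _, l in links)
    counts = [max(1, int(round(spec.n_pipe_sections * l / total))) for _, _, l in links]
    while sum(counts) > spec.n_pipe_sections:
        counts[int(np.argmax(counts))] -= 1
    while sum(counts) < spec.n_pipe_sections:
        counts[int(np.argmin(counts))] += 1
    rows = []
    sec = 0
    for (a, b, length), k in zip(links, counts):
        nodes = [a] + [f"{a}~{b}#{i}" for i in range(1, k)] + [b]
        pieces = rng.dirichlet(np.full(k, 8.0)) * length
        for i in range(k):
            rows.append((f"P{sec:04d}", nodes[i], nodes[i + 1], float(pieces[i]),
                         float(rng.lognormal(math.log(0.2), 0.35)),
                         int(rng.integers(1920, 2011)),
                         _MATERIALS[int(rng.integers(0, len(_MATERIALS)))]))
            sec += 1
    inv = PipeInventory(pd.DataFrame(rows, columns=[
        "section_id", "node_a", "node_b", "length_m", "diameter_m",
        "install_year", "material"]))
    # the location layout is a tree, so DWTP paths are unique: sum link lengths
    import networkx as nx
    g = nx.Graph()
    for a, b, l in links:
        g.add_edge(a, b, length=l)
    dists = {loc: nx.shortest_path_length(g, "DWTP", loc, weight="length")
             for loc in _LOCATIONS}
    return inv, dists


def _build_tree(groups: list[list[str]], rng):
    """Random bifurcating newick with exponential branch lengths; each
    group of leaves is kept monophyletic under the root."""
    import sys
    from skbio import TreeNode

    def clade(leaves) -> str:
        if len(leaves) == 1:
            return f"{leaves[0]}:{rng.exponential(0.1):.6f}"
        # central cuts keep the recursion (and the tree) logarithmically deep
        lo = max(1, len(leaves) // 4)
        hi = max(lo + 1, 3 * len(leaves) // 4)
        cut = int(rng.integers(lo, hi))
        left, right = leaves[:cut], leaves[cut:]
        return (f"({clade(left)},{clade(right)}):{rng.exponential(0.1):.6f}")

    old = sys.getrecursionlimit()
    sys.setrecursionlimit(max(old, 20000))
    try:
        clades = [clade(g) for g in groups if g]
        while len(clades) > 2:  # binary root: fold extra groups pairwise
            b, a = clades.pop(), clades.pop()
            clades.append(f"({a},{b}):{rng.exponential(0.1):.6f}")
        tree = TreeNode.read([f"({','.join(clades)});"])
    finally:
        sys.setrecursionlimit(old)
    return tree


def _solve_retention(mu_pre: np.ndarray, p_base: np.ndarray, model: str,
                     alpha: float) -> np.ndarray:
    """r in (0, 1] with r * p_base = P_model(alpha, r * mu_pre), elementwise."""
    lo = np.zeros_like(mu_pre)
    hi = np.ones_like(mu_pre)
    for _ in range(40):
        mid = (lo + hi) / 2
        f = mid * p_base - predict(model, alpha, mid * mu_pre)
        high = f > 0  # detection exceeds the law -> thin harder
        hi = np.where(high, mid, hi)
        lo = np.where(high, lo, mid)
    r = (lo + hi) / 2
    return np.where(p_base <= 0, 1.0, np.minimum(r, 1.0))


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def generate(spec: SyntheticSpec) -> GeneratedData:
    rng = np.random.default_rng(spec.seed)
    otu_ids = [f"Otu{i:04d}" for i in range(spec.n_otus)]
    months = _calendar_months(spec.start_month, spec.n_months)
    cal = np.array([int(m.split("-")[1]) for m in months])

    # baseline lognormal abundances; the seasonal clusters are the community's
    # dominant members (as in real distribution systems, where the winter and
    # summer clusters are led by the most abundant genera), so they stay
    # detectable year-round at survey sequencing depths
    base_log = rng.normal(spec.abundance_meanlog, spec.abundance_sdlog, spec.n_otus)
    order = np.argsort(base_log)[::-1]
    top_pool = list(order[:sum(spec.clusters.sizes)])
    rng.shuffle(top_pool)
    cluster_members: dict[int, list[str]] = {}
    cursor = 0
    member_of = np.full(spec.n_otus, -1)
    for c, size in enumerate(spec.clusters.sizes, start=1):
        idx = top_pool[cursor:cursor + size]
        cursor += size
        for i in idx:
            member_of[i] = c
        cluster_members[c] = sorted(otu_ids[i] for i in idx)
    if top_pool and spec.clusters.share > 0:
        # rescale member baselines so the clusters jointly hold a realistic
        # share of community reads (their lead taxa dominate the system)
        is_member = member_of > 0
        member_draw = np.exp(rng.normal(0.0, spec.clusters.member_sdlog,
                                        int(is_member.sum())))
        rest_total = np.exp(base_log[~is_member]).sum()
        target_total = spec.clusters.share / (1 - spec.clusters.share) * rest_total
        base_log[is_member] = np.log(member_draw / member_draw.sum() * target_total)

    # seasonal modulation (months x otus)
    season_log = np.zeros((spec.n_months, spec.n_otus))
    for c, peak in enumerate(spec.clusters.peak_calendar_months, start=1):
        phase = np.cos(2 * np.pi * (cal - peak) / spec.clusters.period_months)
        season_log[:, member_of == c] = (spec.clusters.amplitude * phase)[:, None]

    # location-specific OTUs: a moderately abundant band of non-members, so
    # they are actually detectable at their home location (site-specific taxa
    # carry a visible share of reads in real systems)
    n_unique_total = int(spec.unique_fraction * spec.n_otus)
    per_loc = n_unique_total // len(_LOCATIONS)
    non_members = [i for i in order if member_of[i] < 0]  # most abundant first
    eligible = non_members[max(1, len(non_members) // 10):]
    unique_otus: dict[str, list[str]] = {}
    only_at = np.full(spec.n_otus, -1)
    pos = 0
    for li, loc in enumerate(_LOCATIONS):
        idx = eligible[pos:pos + per_loc]
        pos += per_loc
        for i in idx:
            only_at[i] = li
        unique_otus[loc] = sorted(otu_ids[i] for i in idx)

    # pipe network and per-location drift accumulated along links: every
    # link adds independent per-OTU log-abundance increments with variance
    # proportional to its length, so expected divergence between any two
    # locations grows with the pipe length of the path between them.  The
    # drift is confined to the non-member OTUs: it then averages over
    # hundreds of taxa (a stable, cleanly ordered distance decay) and
    # leaves the dominant seasonal members' co-fluctuation untouched.
    inventory, dist_from_dwtp = _build_inventory(spec, rng)
    scale = spec.total_pipe_km * 1000.0 / sum(l for _, _, l in _LAYOUT)
    drifting = member_of < 0
    drift = {"DWTP": np.zeros(spec.n_otus)}
    for a, b, l in _LAYOUT:  # layout is ordered root-outward
        step = np.zeros(spec.n_otus)
        step[drifting] = rng.normal(
            0.0, spec.spatial_decay * math.sqrt(l * scale), int(drifting.sum()))
        drift[b] = drift[a] + step

    # expected proportions per sample
    sample_ids, meta_rows = [], {}
    lam_rows = []
    for t, month in enumerate(months):
        for li, loc in enumerate(_LOCATIONS):
            sid = f"{loc}_{month}"
            sample_ids.append(sid)
            sector = "DWTP" if loc == "DWTP" else f"S{loc[1]}"
            meta_rows[sid] = {"location": loc, "sector": sector,
                              "month_index": t, "calendar_month": month}
            loglam = (base_log + season_log[t] + drift[loc]
                      + rng.normal(0.0, spec.sample_noise_sd, spec.n_otus))
            lam = np.exp(loglam)
            lam[(only_at >= 0) & (only_at != li)] = 0.0
            lam_rows.append(lam / lam.sum())
    lam = np.vstack(lam_rows)

    # water chemistry tied to the seasonal cycle
    for sid, row in meta_rows.items():
        t = row["month_index"]
        c = cal[t]
        summer = math.cos(2 * math.pi * (c - 7) / 12)
        row.update({
            "temperature": round(12 + 9 * summer + rng.normal(0, 1), 2),
            "ph": round(9.1 + 0.2 * summer + rng.normal(0, 0.05), 3),
            "conductivity": round(500 - 120 * summer + rng.normal(0, 20), 1),
            "ammonium": round(max(0.3 - 0.15 * summer + rng.normal(0, 0.03), 0.0), 3),
            "sulfate": round(55 + 8 * math.cos(2 * math.pi * (c - 4) / 12)
                             + rng.normal(0, 2), 2),
            "phosphate": round(max(0.9 + 0.2 * math.cos(2 * math.pi * (c - 4) / 12)
                                   + rng.normal(0, 0.05), 0.0), 3),
            "toc": round(max(1.8 + 0.5 * summer + rng.normal(0, 0.1), 0.2), 3),
            "blend_ratio": round(min(max(0.7 + 0.2 * summer + rng.normal(0, 0.05),
                                         0.0), 1.0), 3),
        })

    # occupancy thinning toward the planted law
    depths = np.clip(rng.lognormal(spec.depth_meanlog, spec.depth_sdlog,
                                   len(sample_ids)),
                     spec.depth_min, spec.depth_max).astype(int)
    month_of = np.repeat(np.arange(spec.n_months), len(_LOCATIONS))
    mean_depth = float(depths.mean())
    keep = np.ones_like(lam, dtype=bool)
    for t in range(spec.n_months):
        rows = np.flatnonzero(month_of == t)
        mu_pre = lam[rows].mean(axis=0)
        p_detect = 1.0 - (1.0 - np.minimum(lam[rows], 1.0)) ** mean_depth
        p_base = p_detect.mean(axis=0)
        r = _solve_retention(mu_pre, p_base, spec.occupancy_model,
                             spec.occupancy_alpha)
        keep[rows] = rng.random((len(rows), spec.n_otus)) < r[None, :]
    lam = np.where(keep, lam, 0.0)
    lam /= lam.sum(axis=1, keepdims=True)

    counts = np.vstack([rng.multinomial(d, p) for d, p in zip(depths, lam)])
    table = OtuTable(sample_ids, otu_ids, counts)
    metadata = SampleMetadata(pd.DataFrame.from_dict(meta_rows, orient="index"))
    tree = _build_tree([cluster_members.get(1, []), cluster_members.get(2, []),
                        sorted(otu_ids[i] for i in range(spec.n_otus)
                               if member_of[i] < 0 or member_of[i] > 2)],
                       rng)
    truth = GroundTruth(
        cluster_members=cluster_members,
        occupancy_model=spec.occupancy_model,
        occupancy_alpha=spec.occupancy_alpha,
        spatial_decay=spec.spatial_decay,
        unique_otus=unique_otus,
        pipe_total_length_m=inventory.total_length,
        pipe_total_surface_m2=inventory.total_surface,
        n_pipe_sections=len(inventory.sections),
        path_length_from_dwtp=dist_from_dwtp,
        depths=dict(zip(sample_ids, (int(d) for d in depths))),
    )
    return GeneratedData(table, metadata, tree, inventory, truth)


# ---------------------------------------------------------------------------
# direct simulation from an occupancy law
# ---------------------------------------------------------------------------

def simulate_occupancy_points(alpha: float = 896.0,
                              model: str = "hanski_gyllenberg",
                              n_otus: int = 4000, n_months: int = 15,
                              n_sites: int = 10, abundance_sdlog: float = 2.5,
                              month_jitter_sdlog: float = 0.5,
                              seed: int = 0) -> pd.DataFrame:
    """Occupancy points drawn exactly from an occupancy-abundance law.

    Per-OTU baseline relative abundances are lognormal (normalized to
    sum to 1), jittered per month; occupancy is binomial,
    f ~ Binomial(n_sites, P_model(alpha, mu)) / n_sites.  Points with
    f = 0 are retained -- they are informative binomial observations --
    which keeps maximum-likelihood estimation of alpha unbiased.
    """
    rng = np.random.default_rng(seed)
    base = rng.lognormal(0.0, abundance_sdlog, n_otus)
    base /= base.sum()
    rows = []
    for t in range(n_months):
        mu = base * rng.lognormal(0.0, month_jitter_sdlog, n_otus)
        p = predict(model, alpha, mu)
        f = rng.binomial(n_sites, p) / n_sites
        rows.append(pd.DataFrame({"otu_id": [f"Otu{i}" for i in range(n_otus)],
                                  "month_index": t, "mu": mu, "f": f,
                                  "n_sites": n_sites}))
    return pd.concat(rows, ignore_index=True)


# ---------------------------------------------------------------------------
# worked miniature fixture
# ---------------------------------------------------------------------------

def worked_fixture() -> tuple[OtuTable, SampleMetadata, dict]:
    """Deterministic 6-OTU x 8-sample dataset with hand-derived constants.

    All rows sum to 100.  The expected-value table carries:

    * ``bray_curtis_s1_s2`` = sum|x-y| / sum(x+y) = 20/200 = 0.1
    * ``jaccard_s1_s2`` = 1 - shared/union = 1 - 4/5 = 0.2
    * ``richness`` per sample (count of nonzero OTUs)
    * ``shannon_s4`` = ln 4 (four equal proportions)
    * ``mic_otu1_otu4``: cutting OTU1 between 10 and 25 and OTU4 between
      25 and 40 puts samples s1-s4 alone in one cell pair (a perfect 4/4
      2x2 grid), so the normalized mutual information -- and hence MIC --
      is exactly 1.
    """
    counts = np.array([
        [40, 30, 20, 10, 0, 0],
        [30, 30, 20, 10, 10, 0],
        [50, 25, 15, 10, 0, 0],
        [25, 25, 25, 25, 0, 0],
        [10, 20, 30, 40, 0, 0],
        [0, 10, 30, 40, 20, 0],
        [10, 10, 20, 40, 10, 10],
        [0, 0, 25, 50, 25, 0],
    ])
    samples = [f"s{i}" for i in range(1, 9)]
    otus = [f"Otu{i}" for i in range(1, 7)]
    table = OtuTable(samples, otus, counts)
    meta = SampleMetadata(pd.DataFrame({
        "location": ["L1", "L2"] * 4,
        "sector": ["S1"] * 8,
        "month_index": [0, 0, 0, 0, 1, 1, 1, 1],
        "calendar_month": ["2010-06"] * 4 + ["2010-07"] * 4,
    }, index=samples))
    expected = {
        "bray_curtis_s1_s2": 0.1,
        "jaccard_s1_s2": 0.2,
        "richness": {"s1": 4, "s2": 5, "s3": 4, "s4": 4,
                     "s5": 4, "s6": 4, "s7": 6, "s8": 3},
        "shannon_s4": math.log(4),
        "mic_otu1_otu4": 1.0,
        "depth": 100,
    }
    return table, meta, expected
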