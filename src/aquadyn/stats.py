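"""Permutation statistics on distance matrices and core-OTU selection.

PERMANOVA, ANOSIM, Mantel and beta-dispersion are implemented directly
on the distance matrix (not via a library call) because each exposes an
exhaustive-enumeration mode used as its own small-sample oracle; all
permutation p-values use the (1 + b) / (1 + n) estimator and are fully
determined by a seed.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .diversity import pcoa
from .distances import DistanceMatrix
from .table import OtuTable

__all__ = [
    "GroupingResult", "permanova", "anosim", "mantel",
    "beta_dispersion", "DispersionResult",
    "core_selection_curve", "pearson_correlations",
]

_EXHAUSTIVE_LIMIT = 8  # n! enumeration is only sane for tiny instances


@dataclass
class GroupingResult:
    statistic: float
    p_value: float | None
    n_permutations: int
    grouping: str
    method: str
    extras: dict = field(default_factory=dict)


def _as_groups(groups) -> np.ndarray:
    g = np.asarray(groups)
    if g.ndim != 1:
        raise ValueError("groups must be one-dimensional")
    return g


def _check_group_sizes(g: np.ndarray, min_size: int = 2) -> None:
    labels, counts = np.unique(g, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    small = labels[counts < min_size]
    if small.size:
        raise ValueError(f"groups with fewer than {min_size} samples: {list(small)}")


def _perm_p(stat_fn, labels: np.ndarray, observed: float, n_perm: int,
            seed, exhaustive: bool) -> tuple[float, int]:
    """Right-tail permutation p-value for a statistic of the label vector."""
    n = len(labels)
    if exhaustive:
        if n > _EXHAUSTIVE_LIMIT:
            raise ValueError(f"exhaustive enumeration limited to n <= {_EXHAUSTIVE_LIMIT}")
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            if stat_fn(labels[list(perm)]) >= observed - 1e-12:
                hits += 1
            total += 1
        return hits / total, total
    rng = np.random.default_rng(seed)
    hits = 0
    for _ in range(n_perm):
        if stat_fn(labels[rng.permutation(n)]) >= observed - 1e-12:
            hits += 1
    return (1 + hits) / (1 + n_perm), n_perm


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def _permanova_stats(d2: np.ndarray, g: np.ndarray) -> tuple[float, float]:
    n = len(g)
    sst = d2[np.triu_indices(n, 1)].sum() / n
    ssw = 0.0
    labels, inverse = np.unique(g, return_inverse=True)
    k = len(labels)
    for j in range(k):
        idx = np.flatnonzero(inverse == j)
        sub = d2[np.ix_(idx, idx)]
        ssw += sub[np.triu_indices(len(idx), 1)].sum() / len(idx)
    ssa = sst - ssw
    if ssw <= 0:
        return math.inf, 1.0
    f = (ssa / (k - 1)) / (ssw / (n - k))
    return f, ssa / sst


def permanova(dm: DistanceMatrix, groups, n_perm: int = 999, seed=None,
              exhaustive: bool = False, grouping: str = "") -> GroupingResult:
    """Permutational multivariate ANOVA (pseudo-F on squared distances).

    ``extras['r_squared']`` carries the fraction of the total sum of
    squared distances explained by the grouping.
    """
    g = _as_groups(groups)
    _check_group_sizes(g)
    d2 = dm.data ** 2

    def stat(labels):
        return _permanova_stats(d2, labels)[0]

    f_obs, r2 = _permanova_stats(d2, g)
    p, n_used = _perm_p(stat, g, f_obs, n_perm, seed, exhaustive)
    return GroupingResult(f_obs, p, n_used, grouping, "permanova",
                          extras={"r_squared": r2})


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def anosim(dm: DistanceMatrix, groups, n_perm: int = 999, seed=None,
           exhaustive: bool = False, grouping: str = "") -> GroupingResult:
    """Analysis of similarities on rank-transformed distances.

    R = (mean between-group rank - mean within-group rank) / (M / 2),
    with M = n(n-1)/2 pairwise distances and average ranks for ties.
    """
    g = _as_groups(groups)
    _check_group_sizes(g)
    n = len(g)
    iu = np.triu_indices(n, 1)
    ranks = sps.rankdata(dm.data[iu])
    m = len(ranks)

    def stat(labels):
        within = labels[iu[0]] == labels[iu[1]]
        return (ranks[~within].mean() - ranks[within].mean()) / (m / 2)

    r_obs = stat(g)
    p, n_used = _perm_p(stat, g, r_obs, n_perm, seed, exhaustive)
    return GroupingResult(r_obs, p, n_used, grouping, "anosim")


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def mantel(dm_a: DistanceMatrix, dm_b: DistanceMatrix, n_perm: int = 999,
           seed=None, exhaustive: bool = False) -> GroupingResult:
    """Mantel correlation of two distance matrices over the same labels.

    Pearson r of the off-diagonal vectors; p by permuting the rows and
    columns of the second matrix.  ``n_perm=0`` skips the permutation
    test (p is None).
    """
    if dm_a.ids != dm_b.ids:
        raise ValueError("Mantel test requires identical labels in identical order")
    n = len(dm_a)
    iu = np.triu_indices(n, 1)
    va = dm_a.data[iu]
    if va.std() == 0 or dm_b.data[iu].std() == 0:
        raise ValueError("Mantel correlation undefined for a constant matrix")

    def r_for(order):
        vb = dm_b.data[np.ix_(order, order)][iu]
        return float(np.corrcoef(va, vb)[0, 1])

    r_obs = r_for(np.arange(n))
    if n_perm == 0 and not exhaustive:
        return GroupingResult(r_obs, None, 0, "", "mantel")
    idx = np.arange(n)
    if exhaustive:
        if n > _EXHAUSTIVE_LIMIT:
            raise ValueError(f"exhaustive enumeration limited to n <= {_EXHAUSTIVE_LIMIT}")
        hits = total = 0
        for perm in itertools.permutations(range(n)):
            if r_for(np.array(perm)) >= r_obs - 1e-12:
                hits += 1
            total += 1
        return GroupingResult(r_obs, hits / total, total, "", "mantel")
    rng = np.random.default_rng(seed)
    hits = sum(r_for(rng.permutation(idx)) >= r_obs - 1e-12 for _ in range(n_perm))
    return GroupingResult(r_obs, (1 + hits) / (1 + n_perm), n_perm, "", "mantel")


# ---------------------------------------------------------------------------
# beta dispersion
# ---------------------------------------------------------------------------

@dataclass
class DispersionResult:
    distances: pd.Series          # per-sample distance to its group centroid
    anova_f: float
    anova_p: float
    tukey: pd.DataFrame | None
    flags: list[str]
    grouping: str = ""


def beta_dispersion(dm: DistanceMatrix, groups, grouping: str = "") -> DispersionResult:
    """Multivariate dispersion: distance of each sample to its group centroid.

    The matrix is embedded by PCoA keeping negative-eigenvalue axes;
    squared distances are corrected by subtracting the imaginary-axis
    component (the standard treatment for semi-metric dissimilarities).
    One-way ANOVA and Tukey HSD are run on the resulting distances.
    """
    g = _as_groups(groups)
    if len(g) != len(dm):
        raise ValueError("groups length must match matrix size")
    emb = pcoa(dm)
    real, imag = emb.coordinates, emb.imag_coordinates
    flags: list[str] = []
    dist = np.zeros(len(g))
    for label in np.unique(g):
        idx = np.flatnonzero(g == label)
        if len(idx) == 1:
            flags.append(f"group {label!r} has a single sample; dispersion 0")
            continue
        c_real = real[idx].mean(axis=0)
        c_imag = imag[idx].mean(axis=0) if imag.size else np.zeros(0)
        d2 = ((real[idx] - c_real) ** 2).sum(axis=1)
        if imag.size:
            d2 = d2 - ((imag[idx] - c_imag) ** 2).sum(axis=1)
        dist[idx] = np.sqrt(np.clip(d2, 0.0, None))
    series = pd.Series(dist, index=dm.ids, name="dist_to_centroid")
    by_group = [dist[g == label] for label in np.unique(g)]
    if all(np.allclose(v, v[0] if len(v) else 0.0) for v in by_group):
        flags.append("zero within-group spread; ANOVA F undefined")
        return DispersionResult(series, math.nan, math.nan, None, flags, grouping)
    f, p = sps.f_oneway(*by_group)
    tukey = None
    if len(np.unique(g)) > 1:
        from statsmodels.stats.multicomp import pairwise_tukeyhsd

        res = pairwise_tukeyhsd(dist, g)
        tukey = pd.DataFrame(res.summary().data[1:], columns=res.summary().data[0])
    return DispersionResult(series, float(f), float(p), tukey, flags, grouping)


# ---------------------------------------------------------------------------
# core-OTU selection
# ---------------------------------------------------------------------------

def core_selection_curve(table: OtuTable, thresholds, mode: str,
                         min_otus: int = 3) -> pd.DataFrame:
    """Mantel correlation of thresholded sub-communities against the full table.

    ``mode='relative_abundance'`` keeps OTUs whose grand mean relative
    abundance exceeds the threshold (a proportion); ``'detection_frequency'``
    keeps OTUs detected in more than that fraction of samples.  For each
    threshold the Bray-Curtis matrix of the retained OTUs is correlated
    (Mantel r, no permutations) against the full-table matrix.  Points
    retaining fewer than ``min_otus`` OTUs are flagged with r = NaN.
    """
    if mode not in ("relative_abundance", "detection_frequency"):
        raise ValueError(f"unknown mode {mode!r}")
    from scipy.spatial.distance import pdist, squareform

    full = DistanceMatrix(table.sample_ids,
                          squareform(pdist(table.counts.astype(float), "braycurtis")),
                          "bray_curtis")
    score = (table.mean_relative_abundance() if mode == "relative_abundance"
             else table.detection_frequency())
    rows = []
    for thr in thresholds:
        keep = score > thr
        n_kept = int(keep.sum())
        if n_kept < min_otus:
            rows.append((thr, n_kept, math.nan, True))
            continue
        sub = table.counts[:, keep].astype(float)
        ok = sub.sum(axis=1) > 0
        if not ok.all():  # a sample emptied by filtering breaks Bray-Curtis
            rows.append((thr, n_kept, math.nan, True))
            continue
        dm = DistanceMatrix(table.sample_ids, squareform(pdist(sub, "braycurtis")),
                            "bray_curtis")
        r = mantel(full, dm, n_perm=0).statistic
        rows.append((thr, n_kept, r, False))
    return pd.DataFrame(rows, columns=["threshold", "n_otus", "mantel_r", "flagged"])


def pearson_correlations(x: pd.DataFrame, y: pd.DataFrame) -> pd.DataFrame:
    """Pairwise Pearson r (and two-sided t-approximation p) between columns.

    Rows are aligned on the shared index; pairs with missing values are
    dropped per comparison.  Used e.g. to relate alpha diversity to
    water chemistry.
    """
    rows = []
    common = x.index.intersection(y.index)
    for cx in x.columns:
        for cy in y.columns:
            a = x.loc[common, cx]
            b = y.loc[common, cy]
            ok = a.notna() & b.notna()
            if ok.sum() < 3:
                continue
            r, p = sps.pearsonr(a[ok], b[ok])
            rows.append((cx, cy, float(r), float(p), int(ok.sum())))
    return pd.DataFrame(rows, columns=["x", "y", "r", "p", "n"])
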