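"""Permutation statistics: trivial geometry, null behavior, exhaustive oracles.

The oracles in this module recompute each statistic from its textbook
definition (explicit double loops over sample pairs) and enumerate
label permutations independently of the library's machinery.
"""

import itertools
import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist, squareform
from scipy.stats import rankdata

from aquadyn.distances import DistanceMatrix
from aquadyn.stats import (anosim, beta_dispersion, core_selection_curve,
                           mantel, pearson_correlations, permanova)
from aquadyn.table import OtuTable


def _dm_from_points(pts):
    pts = np.asarray(pts, dtype=float)
    d = squareform(pdist(pts))
    return DistanceMatrix([f"s{i}" for i in range(len(pts))], d)


# ---------------------------------------------------------------------------
# independent oracles (textbook definitions, brute force)
# ---------------------------------------------------------------------------

def _oracle_permanova_f(d, groups):
    n = len(groups)
    labels = sorted(set(groups))
    k = len(labels)
    sst = sum(d[i, j] ** 2 for i in range(n) for j in range(i + 1, n)) / n
    ssw = 0.0
    for lab in labels:
        idx = [i for i, g in enumerate(groups) if g == lab]
        ssw += sum(d[i, j] ** 2 for i in idx for j in idx if i < j) / len(idx)
    return ((sst - ssw) / (k - 1)) / (ssw / (n - k))


def _oracle_anosim_r(d, groups):
    n = len(groups)
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    ranks = rankdata([d[i, j] for i, j in pairs])
    within = [r for (i, j), r in zip(pairs, ranks) if groups[i] == groups[j]]
    between = [r for (i, j), r in zip(pairs, ranks) if groups[i] != groups[j]]
    m = len(pairs)
    return (np.mean(between) - np.mean(within)) / (m / 2)


def _oracle_perm_p(stat_fn, d, groups, observed):
    hits = total = 0
    groups = list(groups)
    for perm in itertools.permutations(groups):
        if stat_fn(d, list(perm)) >= observed - 1e-12:
            hits += 1
        total += 1
    return hits / total


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

def test_permanova_perfect_separation():
    pts = [[0, 0], [0, 0], [0, 0], [9, 9], [9, 9], [9, 9]]
    res = permanova(_dm_from_points(pts), ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
    assert res.extras["r_squared"] == pytest.approx(1.0)


def test_permanova_null_relabeling():
    rng = np.random.default_rng(5)
    pts = rng.normal(size=(12, 3))
    res = permanova(_dm_from_points(pts), list("ab") * 6, n_perm=199, seed=1)
    assert res.extras["r_squared"] < 0.35
    assert res.p_value > 0.01


def test_permanova_exhaustive_matches_oracle():
    rng = np.random.default_rng(7)
    pts = rng.normal(size=(6, 2))
    pts[:3] += 1.0
    groups = np.array(["a"] * 3 + ["b"] * 3)
    dm = _dm_from_points(pts)
    res = permanova(dm, groups, exhaustive=True)
    f = _oracle_permanova_f(dm.data, list(groups))
    assert res.statistic == pytest.approx(f)
    assert res.p_value == pytest.approx(
        _oracle_perm_p(_oracle_permanova_f, dm.data, list(groups), f))


def test_permanova_singleton_group_rejected():
    with pytest.raises(ValueError, match="fewer than 2"):
        permanova(_dm_from_points([[0], [1], [2]]), ["a", "a", "b"])


# ---------------------------------------------------------------------------
# ANOSIM
# ---------------------------------------------------------------------------

def test_anosim_perfect_separation():
    pts = [[0], [0.1], [0.2], [5], [5.1], [5.2]]
    res = anosim(_dm_from_points(pts), ["a"] * 3 + ["b"] * 3, n_perm=99, seed=0)
    assert res.statistic == pytest.approx(1.0)


def test_anosim_null_mean_near_zero():
    rng = np.random.default_rng(2)
    stats = []
    for _ in range(30):
        pts = rng.normal(size=(8, 2))
        stats.append(anosim(_dm_from_points(pts), list("ab") * 4,
                            n_perm=0 or 19, seed=3).statistic)
    assert abs(np.mean(stats)) < 0.15


def test_anosim_exhaustive_matches_oracle():
    rng = np.random.default_rng(11)
    pts = rng.normal(size=(6, 2))
    groups = ["a", "b", "a", "b", "a", "b"]
    dm = _dm_from_points(pts)
    res = anosim(dm, groups, exhaustive=True)
    r = _oracle_anosim_r(dm.data, groups)
    assert res.statistic == pytest.approx(r)
    assert res.p_value == pytest.approx(
        _oracle_perm_p(_oracle_anosim_r, dm.data, groups, r))


def test_anosim_agrees_with_skbio():
    rng = np.random.default_rng(13)
    pts = rng.normal(size=(9, 2))
    pts[:4] += 0.8
    dm = _dm_from_points(pts)
    groups = ["a"] * 4 + ["b"] * 5
    ours = anosim(dm, groups, n_perm=99, seed=0)
    from skbio.stats.distance import anosim as sk_anosim

    theirs = sk_anosim(dm.to_skbio(), grouping=groups, permutations=99)
    assert ours.statistic == pytest.approx(theirs["test statistic"])


# ---------------------------------------------------------------------------
# Mantel
# ---------------------------------------------------------------------------

def test_mantel_self_correlation():
    rng = np.random.default_rng(3)
    dm = _dm_from_points(rng.normal(size=(6, 2)))
    res = mantel(dm, dm, n_perm=99, seed=0)
    assert res.statistic == pytest.approx(1.0)


def test_mantel_constant_matrix_rejected():
    dm = _dm_from_points([[0], [1], [2], [3]])
    flat = DistanceMatrix(dm.ids, 1 - np.eye(4))
    with pytest.raises(ValueError, match="constant"):
        mantel(dm, flat)


def test_mantel_exhaustive_matches_oracle():
    rng = np.random.default_rng(17)
    a = _dm_from_points(rng.normal(size=(5, 2)))
    b_pts = rng.normal(size=(5, 2))
    b = _dm_from_points(b_pts)
    res = mantel(a, b, exhaustive=True)
    iu = np.triu_indices(5, 1)
    va = a.data[iu]

    def r_of(order):
        vb = b.data[np.ix_(order, order)][iu]
        return np.corrcoef(va, vb)[0, 1]

    r_obs = r_of(np.arange(5))
    hits = sum(r_of(np.array(p)) >= r_obs - 1e-12
               for p in itertools.permutations(range(5)))
    assert res.statistic == pytest.approx(r_obs)
    assert res.p_value == pytest.approx(hits / math.factorial(5))


def test_mantel_agrees_with_skbio():
    rng = np.random.default_rng(19)
    a = _dm_from_points(rng.normal(size=(7, 2)))
    b = _dm_from_points(rng.normal(size=(7, 2)))
    ours = mantel(a, b, n_perm=0)
    from skbio.stats.distance import mantel as sk_mantel

    r, _, _ = sk_mantel(a.to_skbio(), b.to_skbio(), permutations=0)
    assert ours.statistic == pytest.approx(r)


# ---------------------------------------------------------------------------
# beta dispersion
# ---------------------------------------------------------------------------

def test_dispersion_zero_spread_flagged():
    pts = [[0, 0], [0, 0], [5, 5], [5, 5]]
    res = beta_dispersion(_dm_from_points(pts), ["a", "a", "b", "b"])
    assert math.isnan(res.anova_f)
    assert any("undefined" in f for f in res.flags)


def test_dispersion_planted_spread_direction():
    """One tight and one dispersed group: the Tukey difference must have
    the sign of the planted spread difference."""
    rng = np.random.default_rng(23)
    tight = rng.normal(0, 0.05, size=(10, 2))
    wide = rng.normal(0, 2.0, size=(10, 2)) + 10
    dm = _dm_from_points(np.vstack([tight, wide]))
    groups = ["tight"] * 10 + ["wide"] * 10
    res = beta_dispersion(dm, groups)
    assert res.anova_p < 0.01
    assert res.distances[:10].mean() < res.distances[10:].mean()
    row = res.tukey.iloc[0]
    assert row["meandiff"] > 0  # wide minus tight


def test_dispersion_singleton_group_flagged():
    pts = [[0, 0], [0.5, 0], [1, 1], [9, 9]]
    res = beta_dispersion(_dm_from_points(pts), ["a", "a", "a", "b"])
    assert res.distances["s3"] == 0.0
    assert any("single sample" in f for f in res.flags)


def test_dispersion_lower_in_cluster_dominated_seasons(seasonal_data,
                                                       seasonal_events):
    """Seasons dominated by a single planted cluster (winter, summer) show
    lower beta dispersion than the transition seasons where the two
    clusters trade places -- the direction the dominance mechanism
    predicts."""
    import pandas as pd

    from aquadyn.diversity import average_distance, beta_matrix

    dm = average_distance(beta_matrix(ev, "bray_curtis")
                          for ev in seasonal_events[:5])
    seasons = seasonal_data.metadata.column("season", dm.ids)
    res = beta_dispersion(dm, seasons)
    assert res.anova_p < 0.05
    mean_by = pd.Series(res.distances.values, index=seasons).groupby(level=0).mean()
    assert (mean_by[["winter", "summer"]].mean()
            < mean_by[["spring", "autumn"]].mean())


# ---------------------------------------------------------------------------
# core selection
# ---------------------------------------------------------------------------

def _core_table():
    rng = np.random.default_rng(29)
    base = rng.lognormal(0, 2, size=30)
    counts = rng.poisson(base * 20, size=(12, 30)) + np.eye(12, 30, dtype=int)
    return OtuTable([f"s{i}" for i in range(12)], [f"o{j}" for j in range(30)],
                    counts)


def test_core_selection_zero_threshold_keeps_all():
    t = _core_table()
    curve = core_selection_curve(t, [0.0], "detection_frequency")
    assert curve.loc[0, "n_otus"] == t.n_otus
    assert curve.loc[0, "mantel_r"] == pytest.approx(1.0)


@pytest.mark.parametrize("mode", ["relative_abundance", "detection_frequency"])
def test_core_selection_monotone(mode):
    t = _core_table()
    thresholds = np.linspace(0, 0.9, 10)
    curve = core_selection_curve(t, thresholds, mode)
    kept = curve["n_otus"].to_numpy()
    assert (np.diff(kept) <= 0).all()
    rs = curve["mantel_r"].dropna().to_numpy()
    assert (rs <= 1 + 1e-12).all()
    # correlation to the full table only degrades as the filter tightens
    assert (np.diff(rs) <= 1e-6).all()


def test_core_selection_flags_empty():
    t = _core_table()
    curve = core_selection_curve(t, [1.1], "detection_frequency")
    assert bool(curve.loc[0, "flagged"])
    assert math.isnan(curve.loc[0, "mantel_r"])


def test_pearson_helper():
    import pandas as pd

    x = pd.DataFrame({"richness": [1.0, 2, 3, 4, 5]}, index=list("abcde"))
    y = pd.DataFrame({"temp": [2.0, 4, 6, 8, 10],
                      "ph": [5.0, 4, 3, 2, 1]}, index=list("abcde"))
    out = pearson_correlations(x, y).set_index("y")
    assert out.loc["temp", "r"] == pytest.approx(1.0)
    assert out.loc["ph", "r"] == pytest.approx(-1.0)
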