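"""Alpha and beta diversity metrics and principal-coordinate analysis.

Alpha metrics (computed on rarefied counts): observed richness, Shannon
entropy (natural log), the coverage-adjusted nonparametric Shannon
estimator of Chao & Shen, and Shannon evenness H / ln(richness).

Beta metrics: Bray-Curtis and Jaccard (scipy), and unweighted /
weighted-normalized UniFrac (scikit-bio, branch-length normalization
bounding the weighted variant in [0, 1]).

PCoA is the classical Gower double-centering eigendecomposition; axes
for negative eigenvalues are retained (as "imaginary" coordinates) so
that downstream beta-dispersion analysis can apply the standard
imaginary-part correction rather than silently dropping them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .distances import DistanceMatrix
from .table import OtuTable

__all__ = [
    "alpha_diversity", "beta_matrix", "average_distance",
    "average_beta_over_events", "pcoa", "PcoaResult",
]

BETA_METRICS = ("bray_curtis", "jaccard", "unweighted_unifrac", "weighted_unifrac")


# ---------------------------------------------------------------------------
# alpha
# ---------------------------------------------------------------------------

def _shannon(p: np.ndarray) -> float:
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _np_shannon(counts: np.ndarray) -> float:
    # Chao-Shen coverage-adjusted estimator: sample coverage C = 1 - f1/n,
    # adjusted proportions C*p_i, Horvitz-Thompson weighting by the
    # probability 1 - (1 - C p_i)^n of having seen the taxon at all.
    counts = counts[counts > 0]
    n = counts.sum()
    f1 = int((counts == 1).sum())
    coverage = 1.0 - f1 / n
    if coverage <= 0:  # all singletons; leave-one-out floor keeps H finite
        coverage = 1.0 - (f1 - 1) / n if n > 1 else 1.0 / n
    p_adj = coverage * counts / n
    detect = 1.0 - (1.0 - p_adj) ** n
    return float(-(p_adj * np.log(p_adj) / detect).sum())


def alpha_diversity(table: OtuTable) -> pd.DataFrame:
    """Per-sample richness, Shannon H, nonparametric Shannon and evenness.

    Counts are expected to be rarefied to a common depth.  Evenness at
    richness 1 is defined as 0.
    """
    rows = []
    for sid, counts in zip(table.sample_ids, table.counts):
        if counts.sum() == 0:
            raise ValueError(f"all-zero sample {sid!r}")
        p = counts / counts.sum()
        richness = int((counts > 0).sum())
        h = _shannon(p)
        evenness = h / np.log(richness) if richness > 1 else 0.0
        rows.append((sid, richness, h, _np_shannon(counts), evenness))
    return pd.DataFrame(rows, columns=["sample", "richness", "shannon",
                                       "np_shannon", "evenness"]).set_index("sample")


# ---------------------------------------------------------------------------
# beta
# ---------------------------------------------------------------------------

def beta_matrix(table: OtuTable, metric: str, tree=None) -> DistanceMatrix:
    """Pairwise sample dissimilarities under one of the four metrics.

    ``tree`` (a rooted scikit-bio TreeNode whose leaves cover every OTU
    with nonzero count) is required for the UniFrac metrics.
    """
    if metric not in BETA_METRICS:
        raise ValueError(f"unknown metric {metric!r}; choose from {BETA_METRICS}")
    if metric == "bray_curtis":
        data = squareform(pdist(table.counts.astype(float), metric="braycurtis"))
    elif metric == "jaccard":
        data = squareform(pdist(table.counts > 0, metric="jaccard"))
    else:
        if tree is None:
            raise ValueError(f"{metric} requires a phylogeny")
        _check_tree_covers(table, tree)
        from skbio.diversity import beta_diversity

        kwargs = {"taxa": table.otu_ids, "tree": tree}
        if metric == "weighted_unifrac":
            kwargs["normalized"] = True
        skdm = beta_diversity(metric, table.counts, ids=table.sample_ids, **kwargs)
        data = skdm.data
    return DistanceMatrix(table.sample_ids, data, metric=metric)


def _check_tree_covers(table: OtuTable, tree) -> None:
    tips = {t.name for t in tree.tips()}
    present = np.asarray(table.counts).sum(axis=0) > 0
    missing = [o for o, p in zip(table.otu_ids, present) if p and o not in tips]
    if missing:
        raise ValueError(f"OTUs absent from tree: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))


def average_distance(events: Iterable[DistanceMatrix]) -> DistanceMatrix:
    """Element-wise mean of distance matrices sharing one label set."""
    total = None
    ids = None
    metric = ""
    n = 0
    for dm in events:
        if total is None:
            ids, metric = dm.ids, dm.metric
            total = dm.data.copy()
        else:
            if dm.ids != ids:
                raise ValueError("label mismatch between events")
            total += dm.data
        n += 1
    if total is None:
        raise ValueError("no matrices given")
    return DistanceMatrix(ids, total / n, metric=metric)


def average_beta_over_events(events: Iterable[OtuTable], metric: str,
                             tree=None) -> DistanceMatrix:
    """Streaming mean of per-event beta matrices (no event is retained)."""
    return average_distance(beta_matrix(ev, metric, tree) for ev in events)


# ---------------------------------------------------------------------------
# PCoA
# ---------------------------------------------------------------------------

@dataclass
class PcoaResult:
    ids: list[str]
    coordinates: np.ndarray      # axes with positive eigenvalues
    eigenvalues: np.ndarray      # all eigenvalues, descending (negatives kept)
    imag_coordinates: np.ndarray  # axes for negative eigenvalues, |lambda| scaled

    @property
    def proportion_explained(self) -> np.ndarray:
        pos = self.eigenvalues[self.eigenvalues > 0]
        return pos / pos.sum() if pos.size else pos


def pcoa(dm: DistanceMatrix, eps: float = 1e-10) -> PcoaResult:
    """Classical (Gower) principal-coordinate decomposition.

    Negative eigenvalues -- which arise for semi-metric dissimilarities
    such as Bray-Curtis -- are reported, and their axes returned
    separately scaled by sqrt(|lambda|).
    """
    d2 = dm.data ** 2
    n = len(dm)
    centerer = np.eye(n) - np.ones((n, n)) / n
    b = -0.5 * centerer @ d2 @ centerer
    vals, vecs = np.linalg.eigh((b + b.T) / 2)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    scale = np.abs(vals)
    pos = vals > eps * scale.max(initial=1.0)
    neg = vals < -eps * scale.max(initial=1.0)
    coords = vecs[:, pos] * np.sqrt(vals[pos])
    imag = vecs[:, neg] * np.sqrt(-vals[neg])
    return PcoaResult(list(dm.ids), coords, vals, imag)
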