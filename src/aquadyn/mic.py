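"""Maximal information coefficient (MIC) for bivariate association.

MIC scans axis-aligned a x b grids with a * b <= B(n) = max(n^0.6, 4)
and reports the maximum over grids of the normalized mutual information
I(X_binned; Y_binned) / log min(a, b).  It is 1 for any noiseless
functional relationship resolvable at the allowed grid sizes and near 0
for independent variables, which makes it a general-purpose association
screen for relative-abundance profiles.

Two search modes are provided:

* heuristic (default for n > 10): for each row count b the y axis is
  equipartitioned, x-axis cut points are restricted to "clump"
  boundaries (maximal runs of x-consecutive points in a single row,
  capped at ``clump_factor * a`` superclumps), and a dynamic program
  finds the column partition maximizing mutual information.  Both axis
  orientations are searched.  MI is non-decreasing under refinement, so
  the DP's per-column additive decomposition is exact given the clump
  restriction.
* exhaustive (default for n <= 10): every admissible grid is enumerated
  with cuts at every gap between distinct coordinate values.  This is
  the oracle the heuristic is tested against.

Because the statistic depends only on the joint ranks of the data, its
permutation null distribution is a function of n (and the tie
structure) alone; callers screening many pairs of equal length may
therefore share a single null pool (see
:func:`aquadyn.association.robust_associations`).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np

__all__ = ["MicResult", "mic", "mic_score", "slope_sign"]

try:  # pragma: no cover - exercised implicitly
    from numba import njit
except ImportError:  # pragma: no cover
    def njit(*args, **kwargs):
        def wrap(f):
            return f
        return wrap if not (args and callable(args[0])) else args[0]


@dataclass
class MicResult:
    mic: float
    slope_sign: int
    n_points: int
    p_value: float | None = None


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------

def _equipartition_rows(y: np.ndarray, b: int) -> np.ndarray:
    """Row index (0..b-1) per point; tied values never straddle a boundary.

    A run of tied values starting at sorted position s lands in row
    floor(s * b / n): the row whose cumulative share s has reached.
    """
    n = len(y)
    order = np.argsort(y, kind="stable")
    sorted_y = y[order]
    is_start = np.r_[True, sorted_y[1:] != sorted_y[:-1]]
    run_start = np.maximum.accumulate(np.where(is_start, np.arange(n), 0))
    row_sorted = np.minimum((run_start * b) // n, b - 1)
    rows = np.empty(n, dtype=np.int64)
    rows[order] = row_sorted
    return rows


def _clumps(x: np.ndarray, rows: np.ndarray, cap: int) -> np.ndarray:
    """Cumulative row counts at clump boundaries: shape (k+1, b).

    An atom is a run of tied x values (never separable); consecutive
    atoms that are pure and share one row merge into a clump.
    """
    n = len(x)
    b = int(rows.max()) + 1
    order = np.lexsort((rows, x))
    xs = x[order]
    rs = rows[order]
    atom_start = np.flatnonzero(np.r_[True, xs[1:] != xs[:-1]])
    atom_end = np.r_[atom_start[1:], n]
    row_min = np.minimum.reduceat(rs, atom_start)
    row_max = np.maximum.reduceat(rs, atom_start)
    atom_row = np.where(row_min == row_max, row_min, -1)  # -1: mixed atom
    prev = np.r_[-2, atom_row[:-1]]
    new_clump = ~((atom_row >= 0) & (atom_row == prev))
    boundaries = np.r_[atom_start[new_clump], n]
    if len(boundaries) - 1 > cap:  # superclumps: equipartition clump boundaries
        keep = [0]
        target = n / cap
        for bd in boundaries[1:-1]:
            if bd - keep[-1] >= target - 1e-9:
                keep.append(int(bd))
        keep.append(n)
        boundaries = np.asarray(sorted(set(keep)))
    one_hot = np.zeros((n, b))
    one_hot[np.arange(n), rs] = 1.0
    csum = np.vstack([np.zeros(b), np.cumsum(one_hot, axis=0)])
    return csum[boundaries]


@njit(cache=True)
def _dp_best(cum: np.ndarray, a_max: int) -> np.ndarray:  # pragma: no cover
    """vals[l] = max over partitions of all clumps into <= l columns of
    H(P) - H(P, Q), for l = 1..a_max (index 0 unused)."""
    k = cum.shape[0] - 1
    b = cum.shape[1]
    n = 0.0
    for r in range(b):
        n += cum[k, r]
    # column contribution g(s, t)
    g = np.full((k + 1, k + 1), -1e300)
    for s in range(k + 1):
        for t in range(s + 1, k + 1):
            nc = 0.0
            acc = 0.0
            for r in range(b):
                c = cum[t, r] - cum[s, r]
                nc += c
                if c > 0:
                    acc += (c / n) * math.log(c / n)
            if nc > 0:
                acc -= (nc / n) * math.log(nc / n)
            g[s, t] = acc
    lmax = min(a_max, k)
    best = np.full((lmax + 1, k + 1), -1e300)
    for t in range(1, k + 1):
        best[1, t] = g[0, t]
    for l in range(2, lmax + 1):
        for t in range(l, k + 1):
            m = -1e300
            for s in range(l - 1, t):
                v = best[l - 1, s] + g[s, t]
                if v > m:
                    m = v
            best[l, t] = m
    vals = np.full(a_max + 1, -1e300)
    running = -1e300
    for l in range(1, a_max + 1):
        if l <= lmax and best[l, k] > running:
            running = best[l, k]
        vals[l] = running
    return vals


def _entropy(counts: np.ndarray) -> float:
    p = counts[counts > 0] / counts.sum()
    return float(-(p * np.log(p)).sum())


def _heuristic_score(x: np.ndarray, y: np.ndarray, bound: float,
                     clump_factor: int) -> float:
    best = 0.0
    for xs, ys in ((x, y), (y, x)):
        for b in range(2, int(bound // 2) + 1):
            a_max = int(bound // b)
            if a_max < 2:
                break
            rows = _equipartition_rows(ys, b)
            b_eff = int(rows.max()) + 1
            if b_eff < 2:
                continue
            cum = _clumps(xs, rows, cap=clump_factor * a_max)
            h_q = _entropy(cum[-1])
            vals = _dp_best(cum, a_max)
            for a in range(2, a_max + 1):
                mi = h_q + vals[a]
                denom = math.log(min(a, b))
                if denom > 0 and mi > 0:
                    best = max(best, min(mi / denom, 1.0))
    return best


# ---------------------------------------------------------------------------
# exhaustive oracle-mode search
# ---------------------------------------------------------------------------

def _mi_from_bins(xb: np.ndarray, yb: np.ndarray, a: int, b: int) -> float:
    joint = np.zeros((a, b))
    np.add.at(joint, (xb, yb), 1.0)
    n = joint.sum()
    p = joint / n
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = p * np.log(p / (px * py))
    return float(np.nansum(terms))


def _gap_positions(v: np.ndarray) -> np.ndarray:
    sv = np.sort(v)
    return np.flatnonzero(sv[1:] != sv[:-1]) + 1  # cut after this many points


def _bins_for_cuts(v: np.ndarray, cuts: tuple[int, ...]) -> np.ndarray:
    order = np.argsort(v, kind="stable")
    bins = np.empty(len(v), dtype=np.int64)
    edges = [0, *cuts, len(v)]
    for i in range(len(edges) - 1):
        bins[order[edges[i]:edges[i + 1]]] = i
    return bins


def _exhaustive_score(x: np.ndarray, y: np.ndarray, bound: float) -> float:
    xgaps = _gap_positions(x)
    ygaps = _gap_positions(y)
    best = 0.0
    for a in range(2, int(bound // 2) + 1):
        if len(xgaps) < a - 1:
            continue
        for b in range(2, int(bound // a) + 1):
            if len(ygaps) < b - 1:
                continue
            denom = math.log(min(a, b))
            for xc in itertools.combinations(xgaps, a - 1):
                xb = _bins_for_cuts(x, xc)
                for yc in itertools.combinations(ygaps, b - 1):
                    yb = _bins_for_cuts(y, yc)
                    best = max(best, min(_mi_from_bins(xb, yb, a, b) / denom, 1.0))
    return best


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def slope_sign(x: np.ndarray, y: np.ndarray) -> int:
    """Sign of the ordinary least-squares slope of y on x."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    cov = float(((x - x.mean()) * (y - y.mean())).sum())
    tol = 1e-12 * max(1.0, float(np.abs(x).max()) * float(np.abs(y).max())) * len(x)
    if cov > tol:
        return 1
    if cov < -tol:
        return -1
    return 0


def mic_score(x: np.ndarray, y: np.ndarray, *, grid_exponent: float = 0.6,
              clump_factor: int = 15, exhaustive: bool | None = None) -> float:
    """The MIC statistic alone (no slope or p-value bookkeeping)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    n = len(x)
    if n < 8:
        raise ValueError("MIC requires at least 8 points")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("MIC undefined for a constant input")
    bound = max(n ** grid_exponent, 4.0)
    if exhaustive is None:
        exhaustive = n <= 10
    if exhaustive:
        return _exhaustive_score(x, y, bound)
    return _heuristic_score(x, y, bound, clump_factor)


def mic(x, y, *, grid_exponent: float = 0.6, clump_factor: int = 15,
        exhaustive: bool | None = None, n_perm: int = 0,
        seed=None) -> MicResult:
    """MIC with OLS slope sign and an optional permutation p-value.

    The p-value shuffles ``y`` ``n_perm`` times and uses the
    (1 + b) / (1 + n) estimator; ``n_perm=0`` leaves it None.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    score = mic_score(x, y, grid_exponent=grid_exponent,
                      clump_factor=clump_factor, exhaustive=exhaustive)
    p = None
    if n_perm:
        rng = np.random.default_rng(seed)
        hits = 0
        for _ in range(n_perm):
            perm = mic_score(x, rng.permutation(y), grid_exponent=grid_exponent,
                             clump_factor=clump_factor, exhaustive=exhaustive)
            if perm >= score - 1e-12:
                hits += 1
        p = (1 + hits) / (1 + n_perm)
    return MicResult(score, slope_sign(x, y), len(x), p)
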