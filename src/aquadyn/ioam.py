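"""Interspecific occupancy-abundance models (IOAMs).

An IOAM links a taxon's mean relative abundance mu (a proportion) within
a time point to the probability P that it is detected at a monitoring
site in that time point.  Five classical one-parameter forms are
fitted by maximum likelihood (the shape exponent beta fixed at 1):

=====================  =============================
Poisson                P = 1 - exp(-mu)       (no free parameter)
Nachman                P = 1 - exp(-alpha mu)
Hanski-Gyllenberg      P = alpha mu / (1 + alpha mu)
power                  P = min(alpha mu, 1)
negative binomial      P = 1 - (1 + mu / k)^(-k)
=====================  =============================

Occupancy observations come from rarefied tables: per OTU per month,
mu and the detection frequency f are averaged over subsampling events,
so the occupancy count o = f * n_sites is generally fractional.  The
log-likelihood treats the n_sites sites of a month as binomial trials
with fractional successes,

    logL = sum_points [ o ln P + (n_sites - o) ln(1 - P) ],

maximized over ln alpha (ln k) by bounded scalar search.  Goodness of
fit is additionally summarized by the absolute deviance |f - P|
(reported as both mean and sum).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .table import SampleMetadata

__all__ = [
    "MODELS", "predict", "occupancy_points", "event_averaged_profiles",
    "occupancy_from_profiles", "IoamFit", "fit", "compare_models",
    "monthly_alpha_envelope",
]

MODELS = ("poisson", "nachman", "hanski_gyllenberg", "power", "negative_binomial")
_EPS = 1e-12
_BOUNDS = (1e-6, 1e9)


def predict(model: str, param: float | None, mu) -> np.ndarray:
    """Detection probability P(mu) under a model (beta = 1)."""
    mu = np.asarray(mu, dtype=float)
    if (mu < 0).any():
        raise ValueError("mu must be non-negative")
    if model == "poisson":
        return 1.0 - np.exp(-mu)
    if param is None or param <= 0:
        raise ValueError(f"model {model!r} requires a positive parameter")
    if model == "nachman":
        return 1.0 - np.exp(-param * mu)
    if model == "hanski_gyllenberg":
        return param * mu / (1.0 + param * mu)
    if model == "power":
        return np.minimum(param * mu, 1.0)
    if model == "negative_binomial":
        return 1.0 - (1.0 + mu / param) ** (-param)
    raise ValueError(f"unknown model {model!r}")


# ---------------------------------------------------------------------------
# occupancy observations from rarefaction events
# ---------------------------------------------------------------------------

def event_averaged_profiles(events) -> tuple[np.ndarray, np.ndarray, list[str], list[str]]:
    """Per-(sample, OTU) relative abundance and detection rate, averaged
    over rarefaction events.  Streaming; events are not retained."""
    a_sum = d_sum = None
    sample_ids = otu_ids = None
    n = 0
    for ev in events:
        if a_sum is None:
            sample_ids, otu_ids = list(ev.sample_ids), list(ev.otu_ids)
            a_sum = np.zeros((len(sample_ids), len(otu_ids)))
            d_sum = np.zeros_like(a_sum)
        elif list(ev.sample_ids) != sample_ids or list(ev.otu_ids) != otu_ids:
            raise ValueError("events must share sample and OTU sets")
        a_sum += ev.relative_abundance()
        d_sum += ev.counts > 0
        n += 1
    if n == 0:
        raise ValueError("no events given")
    return a_sum / n, d_sum / n, sample_ids, otu_ids


def occupancy_from_profiles(abund: np.ndarray, detect: np.ndarray,
                            otu_ids: list[str], month_of_sample: np.ndarray
                            ) -> pd.DataFrame:
    """(otu, month) occupancy points from event-averaged sample profiles.

    mu = mean relative abundance over the month's samples; f = mean
    detection rate; points with mu = 0 are dropped.
    """
    months, inverse = np.unique(month_of_sample, return_inverse=True)
    frames = []
    for m_idx, month in enumerate(months):
        rows = inverse == m_idx
        n_sites = int(rows.sum())
        if n_sites < 2:
            warnings.warn(f"month {month} has {n_sites} sample(s)")
        mu = abund[rows].mean(axis=0)
        f = detect[rows].mean(axis=0)
        keep = mu > 0
        frames.append(pd.DataFrame({
            "otu_id": np.asarray(otu_ids)[keep], "month_index": month,
            "mu": mu[keep], "f": f[keep], "n_sites": n_sites}))
    return pd.concat(frames, ignore_index=True)


def occupancy_points(events, meta: SampleMetadata) -> pd.DataFrame:
    """Occupancy points (otu_id, month_index, mu, f, n_sites) from events."""
    abund, detect, sample_ids, otu_ids = event_averaged_profiles(events)
    month = meta.column("month_index", sample_ids)
    return occupancy_from_profiles(abund, detect, otu_ids, month)


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------

@dataclass
class IoamFit:
    model: str
    param: float | None      # alpha, or k for the negative binomial
    loglik: float
    mad_mean: float          # mean |f - P|
    mad_sum: float
    n_points: int
    converged: str           # "converged" | "boundary" | "not_applicable"
    clip_events: int         # how many P values hit the [eps, 1-eps] clip


def _loglik(points: pd.DataFrame, model: str, param: float | None
            ) -> tuple[float, int]:
    p = predict(model, param, points["mu"].to_numpy())
    clipped = int(((p < _EPS) | (p > 1 - _EPS)).sum())
    p = np.clip(p, _EPS, 1 - _EPS)
    o = points["f"].to_numpy() * points["n_sites"].to_numpy()
    n = points["n_sites"].to_numpy()
    return float((o * np.log(p) + (n - o) * np.log(1 - p)).sum()), clipped


def fit(points: pd.DataFrame, model: str, min_points: int = 10) -> IoamFit:
    """Maximum-likelihood fit of one model to occupancy points.

    ``points`` needs columns mu, f, n_sites.  The Poisson model has no
    free parameter and is evaluated, not fitted.  The search runs over
    ln(parameter) in [ln 1e-6, ln 1e9]; a solution at a bound is flagged
    "boundary".
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if len(points) < min_points:
        raise ValueError(f"need at least {min_points} occupancy points")

    def stats_at(param):
        ll, clipped = _loglik(points, model, param)
        p = np.clip(predict(model, param, points["mu"].to_numpy()), 0, 1)
        dev = np.abs(points["f"].to_numpy() - p)
        return ll, clipped, float(dev.mean()), float(dev.sum())

    if model == "poisson":
        ll, clipped, mad_mean, mad_sum = stats_at(None)
        return IoamFit(model, None, ll, mad_mean, mad_sum, len(points),
                       "not_applicable", clipped)
    lo, hi = math.log(_BOUNDS[0]), math.log(_BOUNDS[1])
    res = minimize_scalar(lambda t: -_loglik(points, model, math.exp(t))[0],
                          bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    t_hat = float(res.x)
    flag = "converged"
    if t_hat - lo < 1e-4 or hi - t_hat < 1e-4:
        flag = "boundary"
    param = math.exp(t_hat)
    ll, clipped, mad_mean, mad_sum = stats_at(param)
    return IoamFit(model, param, ll, mad_mean, mad_sum, len(points), flag, clipped)


def compare_models(points: pd.DataFrame) -> pd.DataFrame:
    """All five models fitted and ranked by log-likelihood (best first)."""
    fits = [fit(points, m) for m in MODELS]
    frame = pd.DataFrame([{
        "model": f.model, "param": f.param, "loglik": f.loglik,
        "mad_mean": f.mad_mean, "mad_sum": f.mad_sum,
        "converged": f.converged, "clip_events": f.clip_events,
    } for f in fits])
    return frame.sort_values("loglik", ascending=False).reset_index(drop=True)


# ---------------------------------------------------------------------------
# monthly permutation envelope
# ---------------------------------------------------------------------------

def monthly_alpha_envelope(events, meta: SampleMetadata, n_reps: int = 1000,
                           seed=None, model: str = "hanski_gyllenberg",
                           min_points: int = 10) -> pd.DataFrame:
    """Observed per-month alpha against a month-randomization envelope.

    Each permutation shuffles the month labels of the samples *within
    each monitoring location* (spatial structure preserved), rebuilds
    the per-month occupancy points from the event-averaged profiles and
    refits the model per pseudo-month.  Returns per month: alpha_obs,
    and the min / Q1 / Q3 / max of the permuted alphas.
    """
    abund, detect, sample_ids, otu_ids = event_averaged_profiles(events)
    rows = meta.for_samples(sample_ids)
    month = rows["month_index"].to_numpy().copy()
    location = rows["location"].to_numpy()

    def alphas_for(month_labels) -> dict[int, float]:
        pts = occupancy_from_profiles(abund, detect, otu_ids, month_labels)
        out = {}
        for m, sub in pts.groupby("month_index"):
            if len(sub) < min_points:
                warnings.warn(f"month {m}: too few points, omitted")
                continue
            out[int(m)] = fit(sub, model, min_points=min_points).param
        return out

    obs = alphas_for(month)
    rng = np.random.default_rng(seed)
    perm_vals: dict[int, list[float]] = {m: [] for m in obs}
    loc_indices = {l: np.flatnonzero(location == l) for l in np.unique(location)}
    for _ in range(n_reps):
        permuted = month.copy()
        for idx in loc_indices.values():
            permuted[idx] = permuted[rng.permutation(idx)]
        for m, a in alphas_for(permuted).items():
            if m in perm_vals:
                perm_vals[m].append(a)
    recs = []
    for m in sorted(obs):
        vals = np.asarray(perm_vals[m])
        recs.append((m, obs[m], vals.min(), np.quantile(vals, 0.25),
                     np.quantile(vals, 0.75), vals.max(), len(vals)))
    return pd.DataFrame(recs, columns=["month_index", "alpha_obs", "perm_min",
                                       "perm_q1", "perm_q3", "perm_max",
                                       "n_reps"]).set_index("month_index")
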