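"""Time-lag beta-diversity dynamics and divergence from the treatment plant.

The time-lag analysis bins, for every monitoring location separately,
all pairs of that location's samples by their month difference and pools
the binned distances across locations.  An annually cycling community
produces a lag curve that rises to a peak near half the period and dips
back toward the period itself.
"""

from __future__ import annotations

import itertools
import warnings

import numpy as np
import pandas as pd

from .distances import DistanceMatrix
from .table import SampleMetadata

__all__ = ["time_lag_curve", "dwtp_divergence"]


def time_lag_curve(dm: DistanceMatrix, meta: SampleMetadata) -> pd.DataFrame:
    """Mean and variance of within-location pair distances per month lag.

    Returns a frame indexed by lag (months >= 1) with columns
    ``mean``, ``variance`` (population variance) and ``n_pairs``.
    """
    rows = meta.for_samples(dm.ids)
    month = rows["month_index"].to_numpy()
    loc = rows["location"].to_numpy()
    if len(np.unique(month)) < 2:
        raise ValueError("need samples from at least two months")
    by_lag: dict[int, list[float]] = {}
    any_pair = False
    for l in np.unique(loc):
        idx = np.flatnonzero(loc == l)
        for i, j in itertools.combinations(idx, 2):
            lag = abs(int(month[i]) - int(month[j]))
            if lag == 0:
                continue
            by_lag.setdefault(lag, []).append(dm.data[i, j])
            any_pair = True
    if not any_pair:
        raise ValueError("no within-location sample pairs across months")
    recs = []
    for lag in sorted(by_lag):
        vals = np.asarray(by_lag[lag])
        recs.append((lag, vals.mean(), vals.var(), len(vals)))
    return pd.DataFrame(recs, columns=["lag", "mean", "variance", "n_pairs"]
                        ).set_index("lag")


def dwtp_divergence(dm: DistanceMatrix, meta: SampleMetadata,
                    dwtp_sector: str = "DWTP") -> pd.DataFrame:
    """Per-location mean +- sd distance to the same-month treatment-plant sample.

    Months without a plant sample are skipped with a warning.  The
    returned frame has one row per distribution-system location (with
    its sector) plus one aggregate row per sector.
    """
    rows = meta.for_samples(dm.ids)
    is_dwtp = (rows["sector"] == dwtp_sector).to_numpy()
    if not is_dwtp.any():
        raise ValueError(f"no samples with sector {dwtp_sector!r}")
    month = rows["month_index"].to_numpy()
    dwtp_by_month: dict[int, int] = {}
    for i in np.flatnonzero(is_dwtp):
        dwtp_by_month[int(month[i])] = i
    per_loc: dict[str, list[float]] = {}
    loc_sector: dict[str, str] = {}
    skipped = set()
    for i in np.flatnonzero(~is_dwtp):
        m = int(month[i])
        if m not in dwtp_by_month:
            skipped.add(m)
            continue
        l = rows["location"].iloc[i]
        per_loc.setdefault(l, []).append(dm.data[i, dwtp_by_month[m]])
        loc_sector[l] = rows["sector"].iloc[i]
    if skipped:
        warnings.warn(f"months without a DWTP sample skipped: {sorted(skipped)}")
    recs = []
    for l in sorted(per_loc):
        vals = np.asarray(per_loc[l])
        recs.append((l, loc_sector[l], vals.mean(), vals.std(), len(vals)))
    for sec in sorted(set(loc_sector.values())):
        vals = np.concatenate([per_loc[l] for l in per_loc if loc_sector[l] == sec])
        recs.append((f"sector:{sec}", sec, vals.mean(), vals.std(), len(vals)))
    return pd.DataFrame(recs, columns=["location", "sector", "mean", "sd", "n"])
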