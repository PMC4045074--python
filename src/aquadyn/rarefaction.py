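"""Rarefied subsampling of OTU tables.

Each rarefaction event draws, for every sample independently, ``depth``
reads *without replacement* from that sample's reads (a multivariate
hypergeometric draw on the count vector).  Event ``e`` of a plan is
seeded with ``base_seed + e``, so any event is reproducible bit-for-bit
in isolation.  Samples shallower than the depth are dropped once, up
front, and itemized in the plan report -- mirroring the discard of
under-sequenced samples in survey practice.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator

import numpy as np

from .table import OtuTable, ReadReport

__all__ = ["RarefactionPlan", "rarefy", "rarefy_once", "rarefaction_report"]


@dataclass(frozen=True)
class RarefactionPlan:
    depth: int
    n_events: int = 100
    base_seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValueError("depth must be >= 1")
        if self.n_events < 1:
            raise ValueError("n_events must be >= 1")


def rarefaction_report(table: OtuTable, depth: int) -> tuple[list[str], ReadReport]:
    """Sample ids deep enough to rarefy, plus a report of the dropped ones."""
    report = ReadReport()
    totals = table.sample_totals()
    retained = []
    for sid, tot in zip(table.sample_ids, totals):
        if tot >= depth:
            retained.append(sid)
        else:
            report.add_drop(sid, f"total count {tot} < depth {depth}")
    return retained, report


def rarefy_once(table: OtuTable, depth: int, seed: int) -> OtuTable:
    """One rarefaction event; requires every sample total >= depth."""
    totals = table.sample_totals()
    if (totals < depth).any():
        shallow = [s for s, t in zip(table.sample_ids, totals) if t < depth]
        raise ValueError(f"samples shallower than depth {depth}: {shallow}")
    rng = np.random.default_rng(seed)
    out = np.empty_like(table.counts)
    for i in range(table.n_samples):
        row = table.counts[i]
        if totals[i] == depth:
            out[i] = row
        else:
            out[i] = rng.multivariate_hypergeometric(row, depth)
    return OtuTable(list(table.sample_ids), list(table.otu_ids), out, table.taxonomy)


def rarefy(table: OtuTable, plan: RarefactionPlan) -> Iterator[OtuTable]:
    """Yield ``plan.n_events`` rarefied tables (shallow samples dropped).

    The dropped-sample report is available via
    :func:`rarefaction_report`; the first yielded table also carries it
    on ``.report``.
    """
    retained, report = rarefaction_report(table, plan.depth)
    if not retained:
        raise ValueError("no sample is deep enough for the requested depth")
    base = table.select_samples(retained)
    for e in range(plan.n_events):
        event = rarefy_once(base, plan.depth, plan.base_seed + e)
        if e == 0:
            event.report = report
        yield event
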