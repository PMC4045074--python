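"""Core in-memory containers: OTU count tables and per-sample metadata.

An :class:`OtuTable` is a dense samples x OTUs matrix of non-negative
integer read counts with opaque string labels on both axes and optional
consensus taxonomy per OTU.  :class:`SampleMetadata` carries the
spatio-temporal design of a monitoring campaign (location, distribution
sector, month) plus any water-chemistry covariates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = ["OtuTable", "SampleMetadata", "season_of_month", "ReadReport"]

#: calendar month (1..12) -> meteorological season
_SEASONS = {12: "winter", 1: "winter", 2: "winter",
            3: "spring", 4: "spring", 5: "spring",
            6: "summer", 7: "summer", 8: "summer",
            9: "autumn", 10: "autumn", 11: "autumn"}


def season_of_month(calendar_month: int) -> str:
    """Meteorological season of a calendar month (Dec-Feb winter, etc.)."""
    if not 1 <= int(calendar_month) <= 12:
        raise ValueError(f"calendar month out of range: {calendar_month}")
    return _SEASONS[int(calendar_month)]


@dataclass
class ReadReport:
    """Itemized record of rows a reader rejected or adjusted."""

    dropped_samples: list[str] = field(default_factory=list)
    messages: list[str] = field(default_factory=list)

    def add_drop(self, sample_id: str, reason: str) -> None:
        self.dropped_samples.append(sample_id)
        self.messages.append(f"dropped sample {sample_id!r}: {reason}")


def _check_unique(labels: Sequence[str], what: str) -> None:
    seen: set[str] = set()
    for lab in labels:
        if lab in seen:
            raise ValueError(f"duplicate {what} id: {lab!r}")
        seen.add(lab)


@dataclass
class OtuTable:
    """Samples x OTUs count matrix with optional taxonomy.

    Invariants enforced on construction: unique labels on both axes,
    matrix dimensions matching the label lists, integer counts >= 0 and
    a positive total for every retained sample.
    """

    sample_ids: list[str]
    otu_ids: list[str]
    counts: np.ndarray
    taxonomy: dict[str, str] | None = None
    report: ReadReport | None = field(default=None, compare=False, repr=False)

    def __post_init__(self) -> None:
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.otu_ids = [str(o) for o in self.otu_ids]
        _check_unique(self.sample_ids, "sample")
        _check_unique(self.otu_ids, "OTU")
        counts = np.asarray(self.counts)
        if counts.ndim != 2 or counts.shape != (len(self.sample_ids), len(self.otu_ids)):
            raise ValueError(
                f"counts shape {counts.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.otu_ids)} OTUs")
        if not np.issubdtype(counts.dtype, np.integer):
            rounded = np.rint(counts)
            if not np.allclose(counts, rounded):
                raise ValueError("counts must be integers")
            counts = rounded.astype(np.int64)
        else:
            counts = counts.astype(np.int64)
        if (counts < 0).any():
            raise ValueError("negative counts are not allowed")
        if counts.shape[0] and (counts.sum(axis=1) == 0).any():
            bad = [s for s, t in zip(self.sample_ids, counts.sum(axis=1)) if t == 0]
            raise ValueError(f"samples with zero total count: {bad}")
        self.counts = counts

    # -- basic geometry -------------------------------------------------
    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_otus(self) -> int:
        return len(self.otu_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    # -- derived views --------------------------------------------------
    def relative_abundance(self) -> np.ndarray:
        """Per-sample proportions (rows sum to 1)."""
        totals = self.counts.sum(axis=1, keepdims=True).astype(float)
        return self.counts / totals

    def detection_frequency(self) -> np.ndarray:
        """Per-OTU fraction of samples with count > 0."""
        return (self.counts > 0).mean(axis=0)

    def mean_relative_abundance(self) -> np.ndarray:
        """Per-OTU grand mean of per-sample proportions."""
        return self.relative_abundance().mean(axis=0)

    # -- subsetting -----------------------------------------------------
    def select_samples(self, sample_ids: Iterable[str]) -> "OtuTable":
        ids = list(sample_ids)
        idx = [self.sample_index(s) for s in ids]
        return OtuTable(ids, list(self.otu_ids), self.counts[idx], self.taxonomy)

    def select_otus(self, otu_ids: Iterable[str]) -> "OtuTable":
        ids = list(otu_ids)
        pos = {o: j for j, o in enumerate(self.otu_ids)}
        idx = [pos[o] for o in ids]
        tax = None
        if self.taxonomy is not None:
            tax = {o: self.taxonomy[o] for o in ids if o in self.taxonomy}
        return OtuTable(list(self.sample_ids), ids, self.counts[:, idx], tax)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.sample_ids, columns=self.otu_ids)


class SampleMetadata:
    """Per-sample campaign design and water chemistry.

    Wraps a DataFrame indexed by sample id with required columns
    ``location``, ``sector``, ``month_index`` (0-based over the campaign)
    and ``calendar_month`` (ISO ``YYYY-MM``); a ``season`` column is
    derived deterministically from the calendar month.  Any additional
    numeric columns are treated as water-chemistry covariates.
    """

    REQUIRED = ("location", "sector", "month_index", "calendar_month")

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        for col in self.REQUIRED:
            if col not in frame.columns:
                raise ValueError(f"metadata missing required column {col!r}")
        if frame.index.has_duplicates:
            raise ValueError("duplicate sample ids in metadata")
        frame["month_index"] = frame["month_index"].astype(int)
        cal = frame["calendar_month"].astype(str)
        months = cal.str.split("-").str[1].astype(int)
        frame["season"] = [season_of_month(m) for m in months]
        self.frame = frame

    @property
    def sample_ids(self) -> list[str]:
        return list(self.frame.index)

    def for_samples(self, sample_ids: Sequence[str]) -> pd.DataFrame:
        """Rows aligned to ``sample_ids``; every sample must be present."""
        missing = [s for s in sample_ids if s not in self.frame.index]
        if missing:
            raise KeyError(f"samples missing from metadata: {missing}")
        return self.frame.loc[list(sample_ids)]

    def column(self, name: str, sample_ids: Sequence[str]) -> np.ndarray:
        return self.for_samples(sample_ids)[name].to_numpy()

    def chemistry_columns(self) -> list[str]:
        skip = set(self.REQUIRED) | {"season"}
        return [c for c in self.frame.columns
                if c not in skip and pd.api.types.is_numeric_dtype(self.frame[c])]

    def months(self) -> list[int]:
        return sorted(self.frame["month_index"].unique())

    def locations(self) -> list[str]:
        return sorted(self.frame["location"].unique())

    @classmethod
    def from_records(cls, records: Mapping[str, Mapping]) -> "SampleMetadata":
        return cls(pd.DataFrame.from_dict(records, orient="index"))
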