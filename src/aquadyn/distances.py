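"""Labelled symmetric distance matrices.

A thin container that enforces symmetry, a zero diagonal and label
bookkeeping, with helpers for condensed-form access and subsetting.
Conversion to :class:`skbio.DistanceMatrix` is provided for
interoperability.
"""

from __future__ import annotations

from typing import Iterable, Sequence

import numpy as np

__all__ = ["DistanceMatrix"]

_SYM_TOL = 1e-9


class DistanceMatrix:
    def __init__(self, ids: Sequence[str], data, metric: str = ""):
        ids = [str(i) for i in ids]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate labels in distance matrix")
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[0] != data.shape[1]:
            raise ValueError(f"distance matrix must be square, got {data.shape}")
        if data.shape[0] != len(ids):
            raise ValueError("label count does not match matrix size")
        if np.abs(data - data.T).max(initial=0.0) > _SYM_TOL:
            raise ValueError("matrix asymmetric beyond tolerance 1e-9")
        data = (data + data.T) / 2.0
        np.fill_diagonal(data, 0.0)
        if (data < -_SYM_TOL).any():
            raise ValueError("negative distances")
        self.ids = ids
        self.data = data
        self.metric = metric

    # -- geometry ---------------------------------------------------------
    def __len__(self) -> int:
        return len(self.ids)

    @property
    def shape(self):
        return self.data.shape

    def index(self, label: str) -> int:
        return self.ids.index(label)

    def between(self, a: str, b: str) -> float:
        return float(self.data[self.index(a), self.index(b)])

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in scipy condensed order."""
        iu = np.triu_indices(len(self.ids), k=1)
        return self.data[iu]

    def submatrix(self, ids: Iterable[str]) -> "DistanceMatrix":
        ids = list(ids)
        idx = [self.index(i) for i in ids]
        return DistanceMatrix(ids, self.data[np.ix_(idx, idx)], self.metric)

    def to_skbio(self):
        from skbio import DistanceMatrix as SkbioDM

        return SkbioDM(self.data, ids=self.ids)

    def __eq__(self, other) -> bool:
        return (isinstance(other, DistanceMatrix)
                and self.ids == other.ids
                and np.array_equal(self.data, other.data))

    def allclose(self, other: "DistanceMatrix", atol: float = 1e-12) -> bool:
        return self.ids == other.ids and np.allclose(self.data, other.data, atol=atol)
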