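"""Symmetric pairwise dissimilarity matrices over samples or plots."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import CommunityFormatError, LabelMismatchError

_SYMMETRY_TOL = 1e-12


@dataclass
class DistanceMatrix:
    """Square symmetric dissimilarity matrix with zero diagonal.

    ``metric`` tags how the entries were computed (``"turnover-q1"``,
    ``"jaccard"``, ``"horn-morisita"``, ``"euclidean-on-elevation"``, ...).
    """

    labels: list[str]
    values: np.ndarray
    metric: str = "unknown"

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        v = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if v.shape != (n, n):
            raise CommunityFormatError(
                f"distance matrix shape {v.shape} does not match {n} labels"
            )
        if len(set(self.labels)) != n:
            raise CommunityFormatError("duplicate labels in distance matrix")
        if not np.isfinite(v).all():
            raise CommunityFormatError("non-finite distances")
        if np.abs(v - v.T).max(initial=0.0) > _SYMMETRY_TOL:
            raise CommunityFormatError("distance matrix not symmetric")
        if n and np.abs(np.diag(v)).max(initial=0.0) != 0.0:
            raise CommunityFormatError("distance matrix diagonal not exactly 0")
        # store the exactly-symmetrized copy
        self.values = (v + v.T) / 2.0
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries in row-major (scipy ``squareform``) order."""
        iu = np.triu_indices(self.n, k=1)
        return self.values[iu]

    def restrict(self, labels: Sequence[str]) -> "DistanceMatrix":
        """Submatrix over ``labels`` in the given order."""
        idx = {lab: i for i, lab in enumerate(self.labels)}
        missing = [lab for lab in labels if lab not in idx]
        if missing:
            raise LabelMismatchError(f"labels absent from matrix: {missing}")
        sel = [idx[lab] for lab in labels]
        return DistanceMatrix(
            labels=list(labels),
            values=self.values[np.ix_(sel, sel)],
            metric=self.metric,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path: str | Path) -> Path:
        path = Path(path)
        self.to_frame().to_csv(path)
        return path

    @classmethod
    def from_csv(cls, path: str | Path, metric: str = "unknown") -> "DistanceMatrix":
        df = pd.read_csv(path, index_col=0)
        return cls(labels=list(df.index.astype(str)), values=df.to_numpy(), metric=metric)

    @classmethod
    def from_frame(cls, df: pd.DataFrame, metric: str = "unknown") -> "DistanceMatrix":
        return cls(labels=list(df.index.astype(str)), values=df.to_numpy(), metric=metric)
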