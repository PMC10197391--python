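"""Labeled symmetric pairwise matrices — the common currency of the toolkit.

Genetic (FST), geographic (Euclidean / least-cost / circuit) and environmental
distances are all carried as :class:`PairwiseMatrix`: an ordered label list
plus a dense symmetric zero-diagonal array, with CSV round-tripping.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import squareform

__all__ = ["PairwiseMatrix"]


@dataclass
class PairwiseMatrix:
    """Symmetric zero-diagonal matrix over an ordered set of population labels.

    Parameters
    ----------
    labels
        Population identifiers, in matrix row/column order.
    values
        Square symmetric array; diagonal must be zero. Genetic matrices may
        carry small negative entries (unbiased FST estimates); these are
        tolerated and flagged via :attr:`has_negatives`.
    kind
        Tag describing what the entries measure, e.g. ``"genetic"``,
        ``"geographic-euclidean"``, ``"environmental:Bio5"``.
    """

    labels: list[str]
    values: np.ndarray
    kind: str = "distance"

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {n} labels"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("pairwise matrix contains non-finite entries")
        if not np.allclose(self.values, self.values.T, atol=1e-10):
            raise ValueError("pairwise matrix is not symmetric")
        if not np.allclose(np.diag(self.values), 0.0, atol=1e-12):
            raise ValueError("pairwise matrix diagonal is not zero")
        # exact symmetry/zero diagonal after the tolerance check
        self.values = 0.5 * (self.values + self.values.T)
        np.fill_diagonal(self.values, 0.0)

    @property
    def n(self) -> int:
        return len(self.labels)

    @property
    def has_negatives(self) -> bool:
        return bool((self.condensed() < 0).any())

    def condensed(self) -> np.ndarray:
        """Upper-triangle entries as a 1-D vector (scipy condensed order)."""
        return squareform(self.values, checks=False)

    @classmethod
    def from_condensed(
        cls, labels: list[str], vec: np.ndarray, kind: str = "distance"
    ) -> "PairwiseMatrix":
        return cls(labels=list(labels), values=squareform(vec, checks=False), kind=kind)

    def reindex(self, labels: list[str]) -> "PairwiseMatrix":
        """Return a copy with rows/columns reordered to ``labels``."""
        idx = [self.labels.index(str(l)) for l in labels]
        return PairwiseMatrix(
            labels=[str(l) for l in labels],
            values=self.values[np.ix_(idx, idx)],
            kind=self.kind,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index_label="pop_id")

    @classmethod
    def from_csv(cls, path, kind: str = "distance") -> "PairwiseMatrix":
        df = pd.read_csv(path, index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        if list(df.index) != list(df.columns):
            raise ValueError(f"{path}: row and column labels differ")
        return cls(labels=list(df.index), values=df.to_numpy(dtype=float), kind=kind)


def require_aligned(*mats: PairwiseMatrix) -> None:
    """Raise if the matrices do not share an identical ordered label set."""
    ref = mats[0].labels
    for m in mats[1:]:
        if m.labels != ref:
            raise ValueError(
                f"matrix labels not aligned: {m.labels[:3]}... vs {ref[:3]}..."
            )
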