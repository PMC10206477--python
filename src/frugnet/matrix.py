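"""Weighted plant x species visit matrix.

The adjacency matrix of the individual-based bipartite network: rows are
individual plants, columns frugivore species, entries the estimated number of
visits of a species to a plant over the whole study (nonnegative reals).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["VisitMatrix", "merge_visit_matrices"]


@dataclass
class VisitMatrix:
    """Plants x species matrix of whole-study, whole-plant visit estimates.

    Wraps a :class:`pandas.DataFrame` whose index holds plant ids and whose
    columns hold species ids.  Exposes the network quantities used by the
    modularity machinery: the grand total ``F``, plant strengths ``k`` (row
    sums) and species strengths ``d`` (column sums).
    """

    table: pd.DataFrame = field()

    def __post_init__(self) -> None:
        tab = self.table
        if tab.index.has_duplicates or tab.columns.has_duplicates:
            raise ValueError("duplicate plant or species ids in visit matrix")
        values = tab.to_numpy(dtype=float)
        if values.size and np.nanmin(values) < 0:
            raise ValueError("visit matrix entries must be nonnegative")
        if np.isnan(values).any():
            raise ValueError("visit matrix entries must not be missing")
        self.table = tab.astype(float)

    # -- network quantities -------------------------------------------------
    @property
    def values(self) -> np.ndarray:
        return self.table.to_numpy()

    @property
    def plants(self) -> list:
        return list(self.table.index)

    @property
    def species(self) -> list:
        return list(self.table.columns)

    @property
    def F(self) -> float:
        """Grand total of the matrix (total estimated visits)."""
        return float(self.table.to_numpy().sum())

    @property
    def k(self) -> pd.Series:
        """Plant strengths: row sums."""
        return self.table.sum(axis=1)

    @property
    def d(self) -> pd.Series:
        """Species strengths: column sums."""
        return self.table.sum(axis=0)

    @property
    def shape(self) -> tuple[int, int]:
        return self.table.shape

    @property
    def n_links(self) -> int:
        """Number of realized (nonzero) plant-species links."""
        return int((self.table.to_numpy() > 0).sum())

    # -- I/O ----------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "VisitMatrix":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.table.to_csv(path)

    def copy(self) -> "VisitMatrix":
        return VisitMatrix(self.table.copy())


def merge_visit_matrices(a: VisitMatrix, b: VisitMatrix,
                         how: str = "sum") -> VisitMatrix:
    """Fuse two standardized visit matrices into one adjacency matrix.

    Both survey channels (camera traps and scat DNA barcoding) estimate
    whole-plant, whole-study visits in the same units, so their matrices can
    be combined cell-wise over the union of species.  The default rule is the
    cell-wise SUM, which conserves totals (``F_merged = F_a + F_b``); the
    cell-wise mean of the two channels is available via ``how="mean"``.

    Both matrices must describe the same plant set; species sets may differ
    (the union is taken, missing cells count as zero).
    """
    if how not in ("sum", "mean"):
        raise ValueError(f"unknown merge rule: {how!r}")
    if set(a.plants) != set(b.plants):
        raise ValueError("merge requires identical plant sets")
    bt = b.table.reindex(index=a.table.index)
    species = list(a.table.columns) + [s for s in bt.columns
                                       if s not in a.table.columns]
    left = a.table.reindex(columns=species, fill_value=0.0)
    right = bt.reindex(columns=species, fill_value=0.0)
    merged = left + right
    if how == "mean":
        merged = merged / 2.0
    return VisitMatrix(merged)
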