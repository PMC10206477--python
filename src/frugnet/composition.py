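"""Is module membership of plants independent of stand identity?

Plants are cross-tabulated by network module (rows) and stand of origin
(columns); Pearson's chi-squared test of independence (no continuity
correction) assesses whether module composition tracks the range-expansion
gradient, and Haberman adjusted standardized residuals locate the cells where
a stand is over- or under-represented (|r| > 1.96 at the 5% level).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .network import ModulePartition

__all__ = [
    "ChiSquaredResult",
    "stand_module_table",
    "pearson_chi_squared",
    "adjusted_residuals",
]


@dataclass
class ChiSquaredResult:
    statistic: float
    df: int
    p: float
    expected: pd.DataFrame
    observed: pd.DataFrame


def stand_module_table(partition: ModulePartition,
                       plants: pd.DataFrame) -> pd.DataFrame:
    """Contingency table of plant counts: modules (rows) x stands (columns).

    Species nodes are excluded; every plant in the partition must have a
    stand label.  Column order follows first appearance in ``plants``.
    """
    if "stand" not in plants.columns or plants["stand"].isna().any():
        raise ValueError("every plant needs a stand label")
    stands = list(pd.unique(plants["stand"]))
    modules = plants["plant_id"].map(partition.row_modules)
    if modules.isna().any():
        missing = plants.loc[modules.isna(), "plant_id"].tolist()
        raise ValueError(f"plants missing from partition: {missing[:5]}")
    table = pd.crosstab(modules, plants["stand"])
    table = table.reindex(columns=stands, fill_value=0)
    table.index.name = "module"
    return table


def pearson_chi_squared(table: pd.DataFrame) -> ChiSquaredResult:
    """Pearson chi-squared test of independence on a two-way table.

    Expected counts ``E = row_total * col_total / N``; statistic
    ``sum((O - E)^2 / E)`` referred to the chi-squared upper tail with
    ``(rows - 1)(cols - 1)`` degrees of freedom.  No continuity correction.
    """
    O = table.to_numpy(dtype=float)
    if O.sum() <= 0:
        raise ValueError("empty contingency table")
    if (O.sum(axis=1) == 0).any() or (O.sum(axis=0) == 0).any():
        raise ValueError("a module or stand has zero margin")
    stat, p, df, expected = stats.chi2_contingency(O, correction=False)
    return ChiSquaredResult(
        statistic=float(stat), df=int(df), p=float(p),
        expected=pd.DataFrame(expected, index=table.index,
                              columns=table.columns),
        observed=table.astype(float))


def adjusted_residuals(table: pd.DataFrame,
                       flag_at: float = 1.96) -> pd.DataFrame:
    """Haberman adjusted standardized residuals per cell.

    ``r = (O - E) / sqrt(E * (1 - row/N) * (1 - col/N))``; cells with
    ``|r| > flag_at`` mark significant over-/under-representation.  Returns a
    DataFrame with columns ``residual`` and ``flagged`` indexed by
    (module, stand).
    """
    res = pearson_chi_squared(table)
    O = res.observed.to_numpy()
    E = res.expected.to_numpy()
    N = O.sum()
    row = O.sum(axis=1, keepdims=True) / N
    col = O.sum(axis=0, keepdims=True) / N
    r = (O - E) / np.sqrt(E * (1 - row) * (1 - col))
    out = pd.DataFrame(r, index=table.index.rename(table.index.name
                                                   or "module"),
                       columns=table.columns.rename(table.columns.name
                                                    or "stand"))
    tidy = out.stack().rename("residual").reset_index()
    tidy["flagged"] = tidy["residual"].abs() > flag_at
    return tidy.set_index(list(tidy.columns[:2]))
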