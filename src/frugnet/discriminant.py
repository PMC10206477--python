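"""Which plant traits discriminate module membership?

The workflow mirrors standard discriminant practice in ecology:

1. collinearity pruning by variance inflation factor (VIF, threshold 3):
   iteratively drop the variable with the largest VIF until all remain below
   the threshold;
2. forward variable selection by the Wilks' lambda criterion: at each step
   enter the variable minimizing Lambda = det(W)/det(T) (within- over total
   scatter of the selected set), stopping when the best candidate's partial-F
   p-value exceeds the entry threshold;
3. linear discriminant analysis on the selected variables with
   class-proportional priors, reporting the discriminant axes and the
   resubstitution classification accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

__all__ = [
    "VifReport",
    "WilksSelection",
    "LDAModel",
    "vif_prune",
    "wilks_lambda",
    "greedy_wilks",
    "lda_fit_classify",
]


# ----------------------------------------------------------------------
# VIF pruning
# ----------------------------------------------------------------------

@dataclass
class VifReport:
    rounds: list          # list of dicts variable -> VIF, one per round
    dropped: list         # variables removed, in removal order
    retained: list
    threshold: float


def _vif_single(X: np.ndarray, j: int) -> float:
    """VIF of column j: 1 / (1 - R^2) of its regression on the others."""
    y = X[:, j]
    others = np.delete(X, j, axis=1)
    design = np.column_stack([np.ones(len(y)), others])
    coef, *_ = np.linalg.lstsq(design, y, rcond=None)
    resid = y - design @ coef
    tss = ((y - y.mean()) ** 2).sum()
    if tss == 0:
        raise ValueError("constant column has undefined VIF")
    r2 = 1.0 - (resid ** 2).sum() / tss
    r2 = min(r2, 1.0 - 1e-12)
    return float(1.0 / (1.0 - r2))


def vif_prune(traits: pd.DataFrame, threshold: float = 3.0) -> VifReport:
    """Iteratively drop the most collinear variable until all VIF < threshold.

    ``traits`` must be a complete-case numeric table with at least two
    columns; a constant column raises (its VIF is undefined).  Ties on the
    maximum VIF are broken toward the first column.
    """
    if traits.shape[1] < 2:
        raise ValueError("need at least two variables")
    if traits.isna().any().any():
        raise ValueError("missing values: take complete cases first")
    current = list(traits.columns)
    rounds, dropped = [], []
    while True:
        X = traits[current].to_numpy(dtype=float)
        vifs = {v: _vif_single(X, j) for j, v in enumerate(current)}
        rounds.append(vifs)
        worst = max(current, key=lambda v: vifs[v])
        if vifs[worst] < threshold or len(current) == 2:
            if vifs[worst] >= threshold:
                # two mutually collinear variables left: drop one
                dropped.append(worst)
                current = [v for v in current if v != worst]
            break
        dropped.append(worst)
        current = [v for v in current if v != worst]
    return VifReport(rounds=rounds, dropped=dropped, retained=current,
                     threshold=threshold)


# ----------------------------------------------------------------------
# Wilks' lambda forward selection
# ----------------------------------------------------------------------

def _scatter(X: np.ndarray, groups: np.ndarray):
    """Within-group (W) and total (T) scatter matrices."""
    Xc = X - X.mean(axis=0)
    T = Xc.T @ Xc
    W = np.zeros_like(T)
    for g in np.unique(groups):
        Xg = X[groups == g]
        Xg = Xg - Xg.mean(axis=0)
        W += Xg.T @ Xg
    return W, T


def wilks_lambda(X: np.ndarray, groups: np.ndarray) -> float:
    """Wilks' Lambda = det(W) / det(T) for the given variable set."""
    W, T = _scatter(np.atleast_2d(X), groups)
    detT = np.linalg.det(T)
    if detT <= 0:
        raise ValueError("singular total scatter (collinear variables?)")
    return float(np.linalg.det(W) / detT)


@dataclass
class WilksSelection:
    selected: list = field(default_factory=list)
    lambdas: list = field(default_factory=list)   # Lambda after each entry
    partial_f: list = field(default_factory=list)
    p_values: list = field(default_factory=list)
    entry_alpha: float = 0.2


def greedy_wilks(traits: pd.DataFrame, groups,
                 entry_alpha: float = 0.2) -> WilksSelection:
    """Forward selection of discriminating variables by Wilks' lambda.

    At each step the candidate minimizing the overall Lambda of the enlarged
    set enters, provided its partial F

        F = (Lambda_p / Lambda_{p+1} - 1) * (n - g - p) / (g - 1)

    (p variables already in, g groups, n observations) has
    ``p-value <= entry_alpha``.  With ``entry_alpha = 0`` nothing is
    selected.
    """
    groups = np.asarray(groups)
    if len(np.unique(groups)) < 2:
        raise ValueError("need at least two groups")
    n, g = len(groups), len(np.unique(groups))
    remaining = list(traits.columns)
    sel = WilksSelection(entry_alpha=entry_alpha)
    lam_current = 1.0
    while remaining:
        p = len(sel.selected)
        best_var, best_lam = None, None
        for var in remaining:
            cols = sel.selected + [var]
            try:
                lam = wilks_lambda(traits[cols].to_numpy(dtype=float), groups)
            except ValueError:
                raise ValueError(
                    f"variable {var!r} makes the scatter singular")
            if best_lam is None or lam < best_lam:
                best_var, best_lam = var, lam
        df2 = n - g - p
        if df2 <= 0 or best_lam <= 0:
            break
        f_stat = (lam_current / best_lam - 1.0) * df2 / (g - 1)
        p_val = float(stats.f.sf(f_stat, g - 1, df2))
        if p_val > entry_alpha or f_stat <= 0:
            break
        sel.selected.append(best_var)
        sel.lambdas.append(best_lam)
        sel.partial_f.append(float(f_stat))
        sel.p_values.append(p_val)
        remaining.remove(best_var)
        lam_current = best_lam
    return sel


# ----------------------------------------------------------------------
# LDA
# ----------------------------------------------------------------------

@dataclass
class LDAModel:
    classes: list
    class_means: pd.DataFrame
    scalings: np.ndarray          # discriminant axes (columns)
    priors: np.ndarray
    scores: pd.DataFrame          # per-observation discriminant scores
    predicted: pd.Series
    confusion: pd.DataFrame
    accuracy: float               # resubstitution
    accuracy_loo: float | None = None


def lda_fit_classify(traits: pd.DataFrame, groups,
                     loo: bool = False) -> LDAModel:
    """Fit Fisher LDA and classify each plant back to a module.

    Priors are proportional to class sizes.  ``accuracy`` is the
    resubstitution rate (fraction of observations whose predicted class
    equals the true one); set ``loo=True`` to also compute leave-one-out
    cross-validated accuracy.
    """
    X = traits.to_numpy(dtype=float)
    y = np.asarray(groups)
    if traits.isna().any().any():
        raise ValueError("missing values: take complete cases first")
    model = LinearDiscriminantAnalysis(solver="eigen")
    model.fit(X, y)
    pred = model.predict(X)
    classes = list(model.classes_)
    n_axes = min(len(classes) - 1, X.shape[1])
    scores = X @ model.scalings_[:, :n_axes]
    confusion = pd.crosstab(pd.Series(y, name="true"),
                            pd.Series(pred, name="predicted"))
    confusion = confusion.reindex(index=classes, columns=classes,
                                  fill_value=0)
    acc_loo = None
    if loo:
        hits = 0
        for i in range(len(y)):
            keep = np.arange(len(y)) != i
            m = LinearDiscriminantAnalysis(solver="eigen").fit(X[keep],
                                                               y[keep])
            hits += int(m.predict(X[i:i + 1])[0] == y[i])
        acc_loo = hits / len(y)
    return LDAModel(
        classes=classes,
        class_means=pd.DataFrame(model.means_, index=classes,
                                 columns=traits.columns),
        scalings=model.scalings_[:, :n_axes],
        priors=model.priors_,
        scores=pd.DataFrame(scores, index=traits.index,
                            columns=[f"LD{a + 1}" for a in range(n_axes)]),
        predicted=pd.Series(pred, index=traits.index),
        confusion=confusion,
        accuracy=float((pred == y).mean()),
        accuracy_loo=acc_loo)
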