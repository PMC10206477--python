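"""Weighted bipartite modularity and node roles.

The individual-based network has plants on one side, frugivore species on the
other, and standardized visit estimates as link weights.  Module structure is
quantified with Barber's bipartite modularity

    Q = (1/F) * sum_ij [A_ij - k_i * d_j / F] * delta(g_i, g_j)

where ``A`` is the plants x species matrix, ``F`` its grand total, ``k_i`` and
``d_j`` the plant and species strengths, and ``g`` the joint module
assignment.  Q compares the weight falling within modules with the weight
expected if visits were distributed proportionally to node strengths; it is
maximized with a weighted label-propagation heuristic (LPAwb+) plus a
multi-restart wrapper (DIRT) that varies the initial module count.

Significance is assessed against a connectance-preserving null ensemble in
the style of the *vaznull* model: null matrices keep the observed number of
links and the integer grand total, fill cells with probability proportional
to the product of the observed marginals, but do not fix the marginal totals
themselves.  Node topological roles follow the within-module degree (z) and
among-module connectivity (c) of Guimerà-style role analysis, computed on
weights by default.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .matrix import VisitMatrix

__all__ = [
    "ModulePartition",
    "NullEnsemble",
    "barber_modularity",
    "lpawb_plus",
    "dirt_lpawb_plus",
    "vaznull",
    "vaznull_ensemble",
    "node_roles",
    "node_strength",
]


@dataclass
class ModulePartition:
    """Joint module assignment of plant and species nodes.

    ``row_modules`` / ``col_modules`` map plant / species ids to integer
    module labels (0..n_modules-1, in order of first appearance on the plant
    side).  ``Q`` is the Barber modularity of the partition; ``q_history``
    traces Q across optimizer iterations (non-decreasing).
    """

    row_modules: pd.Series
    col_modules: pd.Series
    Q: float
    n_modules: int
    q_history: list = field(default_factory=list)

    def module_of(self, node) -> int:
        if node in self.row_modules.index:
            return int(self.row_modules[node])
        return int(self.col_modules[node])


def _as_arrays(matrix: VisitMatrix):
    A = matrix.values
    F = A.sum()
    if F <= 0:
        raise ValueError("visit matrix has zero total weight")
    return A, A.sum(axis=1), A.sum(axis=0), F


def _q_value(A, k, d, F, row_lab, col_lab) -> float:
    n_mod = int(max(row_lab.max(initial=-1), col_lab.max(initial=-1))) + 1
    within = 0.0
    for m in range(n_mod):
        rows = row_lab == m
        cols = col_lab == m
        if rows.any() and cols.any():
            within += A[np.ix_(rows, cols)].sum()
    K = np.bincount(row_lab, weights=k, minlength=n_mod)
    D = np.bincount(col_lab, weights=d, minlength=n_mod)
    return float((within - (K * D).sum() / F) / F)


def barber_modularity(matrix: VisitMatrix, row_modules, col_modules) -> float:
    """Barber's weighted bipartite modularity of a given joint partition.

    ``row_modules`` / ``col_modules`` map every plant / species id to a
    module label (any hashable; labels are shared across the two sides).
    """
    row_modules = pd.Series(row_modules)
    col_modules = pd.Series(col_modules)
    missing = [n for n in matrix.plants if n not in row_modules.index]
    missing += [n for n in matrix.species if n not in col_modules.index]
    if missing:
        raise ValueError(f"nodes missing from partition: {missing[:5]}")
    labels = pd.unique(pd.concat([row_modules.loc[matrix.plants],
                                  col_modules.loc[matrix.species]]))
    code = {lab: i for i, lab in enumerate(labels)}
    r_lab = np.array([code[row_modules[p]] for p in matrix.plants])
    c_lab = np.array([code[col_modules[s]] for s in matrix.species])
    A, k, d, F = _as_arrays(matrix)
    return _q_value(A, k, d, F, r_lab, c_lab)


# ----------------------------------------------------------------------
# LPAwb+ optimizer
# ----------------------------------------------------------------------

def _compact_labels(row_lab, col_lab):
    """Renumber modules contiguously, ordered by first appearance."""
    order = {}
    for lab in list(row_lab) + list(col_lab):
        if lab not in order:
            order[lab] = len(order)
    return (np.array([order[v] for v in row_lab]),
            np.array([order[v] for v in col_lab]),
            len(order))


def _sweep(A, k, d, F, row_lab, col_lab, rng):
    """One full relabeling pass; returns True if any label changed.

    Each node adopts the partner-side module that maximizes its own
    contribution to Q, holding all other labels fixed (ties broken toward the
    lowest module index); iteration order is a seeded shuffle.
    """
    changed = False
    n_mod = int(max(row_lab.max(), col_lab.max())) + 1
    D = np.bincount(col_lab, weights=d, minlength=n_mod)
    for i in rng.permutation(len(row_lab)):
        gains = np.bincount(col_lab, weights=A[i], minlength=n_mod) \
            - k[i] * D / F
        best = int(np.argmax(gains))  # argmax takes the lowest index on ties
        if gains[best] > gains[row_lab[i]]:
            row_lab[i] = best
            changed = True
    K = np.bincount(row_lab, weights=k, minlength=n_mod)
    for j in rng.permutation(len(col_lab)):
        gains = np.bincount(row_lab, weights=A[:, j], minlength=n_mod) \
            - d[j] * K / F
        best = int(np.argmax(gains))
        if gains[best] > gains[col_lab[j]]:
            col_lab[j] = best
            changed = True
    return changed


def _best_merge(A, k, d, F, row_lab, col_lab):
    """Return (gain, a, b) for the best module-pair merge, or (-inf, -1, -1)."""
    n_mod = int(max(row_lab.max(), col_lab.max())) + 1
    if n_mod < 2:
        return -np.inf, -1, -1
    R = np.zeros((len(row_lab), n_mod))
    R[np.arange(len(row_lab)), row_lab] = 1.0
    C = np.zeros((len(col_lab), n_mod))
    C[np.arange(len(col_lab)), col_lab] = 1.0
    W = R.T @ A @ C  # W[a, b] = weight from rows of a to cols of b
    K = np.bincount(row_lab, weights=k, minlength=n_mod)
    D = np.bincount(col_lab, weights=d, minlength=n_mod)
    best = (-np.inf, -1, -1)
    for a in range(n_mod):
        for b in range(a + 1, n_mod):
            gain = (W[a, b] + W[b, a] - (K[a] * D[b] + K[b] * D[a]) / F) / F
            if gain > best[0]:
                best = (gain, a, b)
    return best


def lpawb_plus(matrix: VisitMatrix, max_steps: int = 1000,
               tolerance: float = 1e-10, rng_seed: int = 0,
               init_row_labels=None) -> ModulePartition:
    """Weighted label propagation for Barber modularity (LPAwb+ style).

    Plants start in their own modules (or in ``init_row_labels``); species
    adopt the plant-side module that maximizes Q, then both sides are
    repeatedly relabeled until no single move helps.  When relabeling stalls,
    the best module-pair merge is applied and relabeling resumes.  Stops when
    neither step improves Q by more than ``tolerance`` or after ``max_steps``
    passes; the returned Q is a local maximum under single relabels and pair
    merges.  Deterministic given ``rng_seed``.
    """
    A, k, d, F = _as_arrays(matrix)
    rng = np.random.default_rng(rng_seed)
    r, c = A.shape
    if init_row_labels is None:
        row_lab = np.arange(r)
    else:
        row_lab = np.asarray(init_row_labels, dtype=int).copy()
        if row_lab.shape != (r,):
            raise ValueError("init_row_labels must have one label per plant")
    # seed the species side greedily from the plant-side modules
    col_lab = np.zeros(c, dtype=int)
    n_mod = int(row_lab.max()) + 1
    for j in range(c):
        gains = np.bincount(row_lab, weights=A[:, j], minlength=n_mod)
        col_lab[j] = int(np.argmax(gains))
    row_lab, col_lab, _ = _compact_labels(row_lab, col_lab)

    q = _q_value(A, k, d, F, row_lab, col_lab)
    history = [q]
    for _ in range(max_steps):
        improved = False
        while _sweep(A, k, d, F, row_lab, col_lab, rng):
            row_lab, col_lab, _ = _compact_labels(row_lab, col_lab)
            q_new = _q_value(A, k, d, F, row_lab, col_lab)
            history.append(q_new)
            if q_new - q > tolerance:
                improved = True
            q = q_new
        # merge stage: accept strictly improving merges, and Q-neutral ones
        # (they collapse structureless fragments without changing Q)
        gain, a, b = _best_merge(A, k, d, F, row_lab, col_lab)
        if a >= 0 and gain >= -1e-12:
            row_lab[row_lab == b] = a
            col_lab[col_lab == b] = a
            row_lab, col_lab, _ = _compact_labels(row_lab, col_lab)
            q = _q_value(A, k, d, F, row_lab, col_lab)
            history.append(q)
            improved = True
        if not improved:
            break
    row_lab, col_lab, n_mod = _compact_labels(row_lab, col_lab)
    q = _q_value(A, k, d, F, row_lab, col_lab)
    history.append(q)
    return ModulePartition(
        row_modules=pd.Series(row_lab, index=matrix.plants),
        col_modules=pd.Series(col_lab, index=matrix.species),
        Q=q, n_modules=n_mod, q_history=history)


def dirt_lpawb_plus(matrix: VisitMatrix, n_restarts: int = 20,
                    rng_seed: int = 0, max_steps: int = 1000,
                    tolerance: float = 1e-10) -> ModulePartition:
    """Multi-restart LPAwb+ varying the initial module count.

    Restart 0 reproduces :func:`lpawb_plus` (every plant its own module);
    subsequent restarts start from random plant groupings into 2, 3, ...
    modules (cycling up to ``min(n_plants, n_species) + 1``).  Returns the
    best-Q partition; deterministic given ``rng_seed``.
    """
    if n_restarts < 1:
        raise ValueError("n_restarts must be >= 1")
    r, c = matrix.shape
    seeds = np.random.SeedSequence(rng_seed).spawn(n_restarts)
    best = lpawb_plus(matrix, max_steps, tolerance, rng_seed=rng_seed)
    max_init = max(2, min(r, c) + 1)
    for j in range(1, n_restarts):
        child = np.random.default_rng(seeds[j])
        m = 2 + (j - 1) % (max_init - 1)
        init = child.integers(0, m, size=r)
        cand = lpawb_plus(matrix, max_steps, tolerance,
                          rng_seed=int(child.integers(2 ** 31)),
                          init_row_labels=init)
        if cand.Q > best.Q:
            best = cand
    return best


# ----------------------------------------------------------------------
# Connectance-preserving null model
# ----------------------------------------------------------------------

def _integer_matrix(A: np.ndarray) -> np.ndarray:
    """Round weights to integers, keeping every observed link occupied."""
    M = np.rint(A).astype(np.int64)
    M[(A > 0) & (M == 0)] = 1
    return M


def vaznull(A: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """One connectance-preserving null matrix from integer counts ``A``.

    Cell probabilities are proportional to the product of the observed
    marginals.  Single interactions are placed sequentially — first pairing
    uncovered rows with uncovered columns so every row and column gains at
    least one link — until the observed link count is reached; the remaining
    interactions are distributed multinomially over the occupied cells.  The
    null conserves the link count and the grand total but not the marginal
    totals.
    """
    A = np.asarray(A)
    k = A.sum(axis=1).astype(float)
    d = A.sum(axis=0).astype(float)
    if (k <= 0).any() or (d <= 0).any():
        raise ValueError("every row and column needs at least one interaction")
    r, c = A.shape
    L = int((A > 0).sum())
    total = int(A.sum())
    P = np.outer(k, d)
    occupied = np.zeros((r, c), dtype=bool)

    def draw(mask):
        p = np.where(mask, P, 0.0).ravel()
        idx = rng.choice(r * c, p=p / p.sum())
        return np.unravel_index(idx, (r, c))

    row_cov = np.zeros(r, dtype=bool)
    col_cov = np.zeros(c, dtype=bool)
    while not (row_cov.all() and col_cov.all()):
        if not row_cov.all() and not col_cov.all():
            mask = ~occupied & np.outer(~row_cov, ~col_cov)
        elif not row_cov.all():
            mask = ~occupied & ~row_cov[:, None]
        else:
            mask = ~occupied & ~col_cov[None, :]
        i, j = draw(mask)
        occupied[i, j] = True
        row_cov[i] = col_cov[j] = True
    while occupied.sum() < L:
        i, j = draw(~occupied)
        occupied[i, j] = True

    null = occupied.astype(np.int64)
    remaining = total - int(occupied.sum())
    if remaining > 0:
        p = np.where(occupied, P, 0.0).ravel()
        extra = rng.multinomial(remaining, p / p.sum())
        null += extra.reshape(r, c)
    return null


@dataclass
class NullEnsemble:
    """Observed Q against a connectance-preserving null distribution."""

    q_obs: float
    q_null: np.ndarray
    n_null: int
    rng_seed: int

    @property
    def mean(self) -> float:
        return float(np.mean(self.q_null))

    @property
    def sd(self) -> float:
        return float(np.std(self.q_null, ddof=1))

    @property
    def z(self) -> float:
        return (self.q_obs - self.mean) / self.sd

    @property
    def p_normal(self) -> float:
        """Upper-tail p-value from the normal approximation of z."""
        return float(stats.norm.sf(self.z))

    @property
    def p_empirical(self) -> float:
        """Rank-based p with the +1 correction."""
        return float((1 + (self.q_null >= self.q_obs).sum())
                     / (self.n_null + 1))


def vaznull_ensemble(matrix: VisitMatrix, n_null: int = 100,
                     rng_seed: int = 0, n_restarts: int = 3,
                     max_steps: int = 1000,
                     tolerance: float = 1e-10) -> NullEnsemble:
    """Significance of the observed modularity against vaznull-style nulls.

    The observed Q is maximized on the (unrounded) matrix; each of ``n_null``
    null matrices is built from the integer-rounded matrix (occupied cells
    floored at one interaction, since the null allocates discrete
    interactions) and its Q maximized the same way.
    """
    if n_null < 2:
        raise ValueError("n_null must be >= 2")
    obs = dirt_lpawb_plus(matrix, n_restarts=n_restarts, rng_seed=rng_seed,
                          max_steps=max_steps, tolerance=tolerance)
    M = _integer_matrix(matrix.values)
    seeds = np.random.SeedSequence([rng_seed, 7]).spawn(n_null)
    q_null = np.empty(n_null)
    for b in range(n_null):
        rng = np.random.default_rng(seeds[b])
        null = vaznull(M, rng)
        null_vm = VisitMatrix(pd.DataFrame(
            null, index=matrix.plants, columns=matrix.species))
        q_null[b] = dirt_lpawb_plus(
            null_vm, n_restarts=n_restarts,
            rng_seed=int(rng.integers(2 ** 31)),
            max_steps=max_steps, tolerance=tolerance).Q
    return NullEnsemble(q_obs=obs.Q, q_null=q_null, n_null=n_null,
                        rng_seed=rng_seed)


# ----------------------------------------------------------------------
# Node roles
# ----------------------------------------------------------------------

def node_strength(matrix: VisitMatrix, side: str = "both") -> pd.Series:
    """Node strength (sum of link weights): plants' row sums, species'
    column sums.  ``side`` selects ``"plants"``, ``"species"`` or ``"both"``
    (concatenated)."""
    if side == "plants":
        return matrix.k
    if side == "species":
        return matrix.d
    if side == "both":
        return pd.concat([matrix.k, matrix.d])
    raise ValueError(f"unknown side {side!r}")


def node_roles(matrix: VisitMatrix, partition: ModulePartition,
               weighted: bool = True) -> pd.DataFrame:
    """Topological roles: among-module connectivity c and within-module
    degree z for every node.

    With ``kappa[i, t]`` the interaction of node i with partners in module t
    (link weights when ``weighted``, link counts otherwise) and ``k_i`` its
    total, ``c_i = 1 - sum_t (kappa[i,t]/k_i)**2`` measures how evenly the
    node's interactions spread among modules (0 = all within one module) and
    ``z_i`` standardizes the node's within-own-module interaction against
    same-side nodes of its module.  Nodes without interactions are dropped
    with a warning; z is set to 0 in modules with zero spread.
    """
    A = matrix.values if weighted else (matrix.values > 0).astype(float)
    n_mod = partition.n_modules
    r_lab = partition.row_modules.loc[matrix.plants].to_numpy()
    c_lab = partition.col_modules.loc[matrix.species].to_numpy()

    rows = []
    for side, labels, partner_labels, ids, mat in (
            ("plant", r_lab, c_lab, matrix.plants, A),
            ("species", c_lab, r_lab, matrix.species, A.T)):
        kappa = np.zeros((len(ids), n_mod))
        for t in range(n_mod):
            kappa[:, t] = mat[:, partner_labels == t].sum(axis=1)
        k_tot = kappa.sum(axis=1)
        zero = k_tot == 0
        if zero.any():
            warnings.warn(
                f"{int(zero.sum())} {side} node(s) without interactions "
                "excluded from role analysis")
        own = kappa[np.arange(len(ids)), labels]
        z = np.zeros(len(ids))
        for m in np.unique(labels):
            members = (labels == m) & ~zero
            if members.sum() == 0:
                continue
            spread = own[members].std(ddof=0)
            if spread == 0:
                warnings.warn(
                    f"module {m} has zero within-module spread on the "
                    f"{side} side; z set to 0")
                continue
            z[members] = (own[members] - own[members].mean()) / spread
        with np.errstate(invalid="ignore", divide="ignore"):
            c = 1.0 - ((kappa / k_tot[:, None]) ** 2).sum(axis=1)
        for idx, node in enumerate(ids):
            if zero[idx]:
                continue
            rows.append((node, side, int(labels[idx]),
                         float(c[idx]), float(z[idx]), float(k_tot[idx])))
    return pd.DataFrame(
        rows, columns=["node", "side", "module", "c", "z", "strength"]
    ).set_index("node")
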