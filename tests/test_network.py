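"""Barber modularity, label propagation, null model and node roles."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import normalized_mutual_info_score

from frugnet import (VisitMatrix, barber_modularity, dirt_lpawb_plus,
                     lpawb_plus, node_roles, node_strength, vaznull,
                     vaznull_ensemble)
from frugnet.network import _integer_matrix

from .oracles import brute_force_barber_q


def _vm(A):
    A = np.asarray(A, dtype=float)
    return VisitMatrix(pd.DataFrame(
        A, index=[f"p{i}" for i in range(A.shape[0])],
        columns=[f"s{j}" for j in range(A.shape[1])]))


def test_single_module_partition_has_zero_q():
    m = _vm([[3, 1], [2, 5]])
    labels_r = {p: 0 for p in m.plants}
    labels_c = {s: 0 for s in m.species}
    assert barber_modularity(m, labels_r, labels_c) == pytest.approx(0.0)


def test_two_equal_blocks_give_q_half():
    m = _vm([[5, 0], [0, 5]])
    q = barber_modularity(m, {"p0": 0, "p1": 1}, {"s0": 0, "s1": 1})
    assert q == pytest.approx(0.5)


def test_q_invariant_under_module_relabeling():
    rng = np.random.default_rng(1)
    m = _vm(rng.integers(1, 6, size=(4, 3)))
    r = {"p0": "a", "p1": "b", "p2": "a", "p3": "c"}
    c = {"s0": "a", "s1": "b", "s2": "c"}
    swap = {"a": "z", "b": "y", "c": "x"}
    q1 = barber_modularity(m, r, c)
    q2 = barber_modularity(m, {k: swap[v] for k, v in r.items()},
                           {k: swap[v] for k, v in c.items()})
    assert q1 == pytest.approx(q2, abs=1e-12)


def test_missing_node_rejected():
    m = _vm([[1, 2], [3, 4]])
    with pytest.raises(ValueError, match="missing"):
        barber_modularity(m, {"p0": 0}, {"s0": 0, "s1": 0})


def test_recomputed_q_matches_stored_q(default_study):
    part = dirt_lpawb_plus(default_study["matrix"], n_restarts=3, rng_seed=0)
    q = barber_modularity(default_study["matrix"], part.row_modules,
                          part.col_modules)
    assert q == pytest.approx(part.Q, abs=1e-12)


def test_block_diagonal_matrix_recovered_exactly():
    """Uniform diagonal blocks are the optimal partition and are returned."""
    m = _vm([[5, 5, 0, 0], [5, 5, 0, 0], [0, 0, 5, 5], [0, 0, 5, 5]])
    part = lpawb_plus(m, rng_seed=0)
    assert part.n_modules == 2
    assert part.row_modules["p0"] == part.row_modules["p1"]
    assert part.row_modules["p2"] == part.row_modules["p3"]
    expected = barber_modularity(
        m, {"p0": 0, "p1": 0, "p2": 1, "p3": 1},
        {"s0": 0, "s1": 0, "s2": 1, "s3": 1})
    assert part.Q == pytest.approx(expected, abs=1e-12)
    assert part.Q == pytest.approx(brute_force_barber_q(m.values), abs=1e-9)
    assert expected == pytest.approx(0.5)  # equal block weights


def test_structureless_matrix_collapses_to_one_module():
    m = _vm(np.full((4, 4), 2.0))
    part = lpawb_plus(m, rng_seed=0)
    assert part.Q == pytest.approx(0.0, abs=1e-12)
    assert part.n_modules == 1


def test_q_history_is_monotone(default_study):
    part = lpawb_plus(default_study["matrix"], rng_seed=1)
    hist = np.array(part.q_history)
    assert (np.diff(hist) >= -1e-12).all()


def test_dirt_single_restart_equals_plain_run(default_study):
    m = default_study["matrix"]
    a = lpawb_plus(m, rng_seed=7)
    b = dirt_lpawb_plus(m, n_restarts=1, rng_seed=7)
    assert a.Q == b.Q
    assert (a.row_modules == b.row_modules).all()


def test_dirt_never_worse_than_single_run(default_study):
    m = default_study["matrix"]
    assert dirt_lpawb_plus(m, n_restarts=10, rng_seed=3).Q >= \
        lpawb_plus(m, rng_seed=3).Q - 1e-12


def test_optimizer_matches_exhaustive_search_on_small_matrices():
    """On random matrices up to 4x4 the heuristic never exceeds, and almost
    always attains, the exhaustively enumerated optimum."""
    rng = np.random.default_rng(5)
    match = 0
    n = 20
    for i in range(n):
        r, c = rng.integers(2, 5, size=2)
        A = rng.integers(0, 5, size=(r, c)).astype(float)
        A[A.sum(axis=1) == 0, 0] += 1
        A[:, A.sum(axis=0) == 0] += 1
        part = dirt_lpawb_plus(_vm(A), n_restarts=10, rng_seed=i)
        opt = brute_force_barber_q(A)
        assert part.Q <= opt + 1e-9
        match += int(abs(part.Q - opt) <= 1e-9)
    assert match >= 0.9 * n


def test_planted_modules_recovered_with_full_information(modular_study):
    true = modular_study["true"]
    part = dirt_lpawb_plus(modular_study["matrix"], n_restarts=5, rng_seed=2)
    nodes = list(true.plant_modules.index) + list(true.species_modules.index)
    truth = pd.concat([true.plant_modules, true.species_modules]).loc[nodes]
    pred = pd.concat([part.row_modules, part.col_modules]).loc[nodes]
    assert normalized_mutual_info_score(truth, pred) >= 0.95
    assert part.n_modules == 3


def test_empty_matrix_rejected():
    with pytest.raises(ValueError):
        lpawb_plus(_vm([[0.0, 0.0], [0.0, 0.0]]))


# ----------------------------------------------------------------------
# Null model
# ----------------------------------------------------------------------

def test_null_preserves_links_totals_and_connectivity():
    rng = np.random.default_rng(0)
    A = rng.integers(0, 6, size=(8, 5))
    A[A.sum(axis=1) == 0, 0] += 1
    A[:, A.sum(axis=0) == 0] += 1
    L, total = (A > 0).sum(), A.sum()
    marginals_varied = False
    for b in range(30):
        null = vaznull(A, np.random.default_rng(b))
        assert (null > 0).sum() == L
        assert null.sum() == total
        assert (null.sum(axis=1) > 0).all()
        assert (null.sum(axis=0) > 0).all()
        marginals_varied |= (null.sum(axis=1) != A.sum(axis=1)).any()
    assert marginals_varied  # marginal totals are NOT conserved


def test_integer_rounding_keeps_occupied_cells():
    A = np.array([[0.3, 2.6], [0.0, 1.2]])
    M = _integer_matrix(A)
    assert ((M > 0) == (A > 0)).all()
    assert M[0, 0] == 1  # floored, not rounded away


def test_zero_margin_matrix_rejected_by_null():
    with pytest.raises(ValueError):
        vaznull(np.array([[1, 0], [2, 0]]), np.random.default_rng(0))


def test_modular_network_is_significant_against_nulls(modular_study):
    ens = vaznull_ensemble(modular_study["matrix"], n_null=30, rng_seed=0,
                           n_restarts=2)
    assert ens.z > 3.09           # p < 0.001
    assert ens.p_normal < 1e-3
    assert ens.p_empirical <= 1 / 31 + 1e-12


# ----------------------------------------------------------------------
# Node roles and strength
# ----------------------------------------------------------------------

def test_within_module_specialist_has_zero_c(modular_study):
    m = modular_study["matrix"]
    part = dirt_lpawb_plus(m, n_restarts=3, rng_seed=0)
    roles = node_roles(m, part)
    # a plant visited only by species of its own module
    A = m.table
    for plant in m.plants:
        partners = A.columns[A.loc[plant] > 0]
        mods = {part.col_modules[s] for s in partners}
        if mods == {part.row_modules[plant]}:
            assert roles.loc[plant, "c"] == pytest.approx(0.0)
            break
    else:
        pytest.fail("no within-module specialist found")


def test_equal_spread_over_t_modules_gives_closed_form_c():
    m = _vm([[1, 1, 1]])
    part = dirt_lpawb_plus(m, rng_seed=0)
    # force three modules: one species each
    part.col_modules[:] = [0, 1, 2]
    part.row_modules[:] = [0]
    part.n_modules = 3
    roles = node_roles(m, part)
    assert roles.loc["p0", "c"] == pytest.approx(1 - 1 / 3)


def test_node_roles_match_hand_computation():
    """3x2 matrix, modules {p0,p1,s0} and {p2,s1}: kappa and z by hand."""
    A = np.array([[4.0, 1.0], [2.0, 0.0], [0.0, 3.0]])
    m = _vm(A)
    part = dirt_lpawb_plus(m, rng_seed=0)
    part.row_modules[:] = [0, 0, 1]
    part.col_modules[:] = [0, 1]
    part.n_modules = 2
    roles = node_roles(m, part, weighted=True)
    # p0: kappa = (4, 1), k = 5 -> c = 1 - (16+1)/25
    assert roles.loc["p0", "c"] == pytest.approx(1 - 17 / 25)
    # plant-side module 0 own-kappas: p0 -> 4, p1 -> 2; sd = 1, mean = 3
    assert roles.loc["p0", "z"] == pytest.approx(1.0)
    assert roles.loc["p1", "z"] == pytest.approx(-1.0)
    # p2 alone in its module: zero spread -> z = 0 (warned)
    assert roles.loc["p2", "z"] == 0.0


def test_strengths_conserve_grand_total(default_study):
    m = default_study["matrix"]
    assert node_strength(m, "plants").sum() == pytest.approx(m.F)
    assert node_strength(m, "species").sum() == pytest.approx(m.F)
    both = node_strength(m, "both")
    assert len(both) == len(m.plants) + len(m.species)


def test_strength_equivariant_under_row_permutation():
    rng = np.random.default_rng(3)
    A = rng.uniform(0, 5, size=(5, 3))
    m = _vm(A)
    perm = rng.permutation(5)
    m2 = VisitMatrix(m.table.iloc[perm])
    s1 = node_strength(m, "plants")
    s2 = node_strength(m2, "plants")
    assert (s1.loc[s2.index] == s2).all()
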