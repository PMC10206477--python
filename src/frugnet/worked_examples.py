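"""Desk-checkable reference computations.

These run the package's own operations on the small worked inputs of the
reference survey — the standardization and seed-rain arithmetic examples, the
module x stand contingency table and the Table-style visit bookkeeping — so
the numerical core can be verified in milliseconds without any dataset.
"""

from __future__ import annotations

import pandas as pd

from . import reference
from .composition import pearson_chi_squared, adjusted_residuals
from .matrix import VisitMatrix
from .seedrain import SeedRainTable, estimate_dispersed_seeds, species_shares
from .standardize import coverage_fraction_for_cover, standardize_camera

__all__ = [
    "seed_rain_worked_example",
    "camera_worked_example",
    "reference_contingency",
    "reference_bookkeeping",
    "verify_reference",
]


def seed_rain_worked_example() -> float:
    """Viable seeds dispersed by five fox visits to plant C106.

    Feeding rate 7.4 cones/visit, 97% undamaged seeds, 5.22 seeds/cone, 21%
    viability -> 39.3 viable seeds.
    """
    visits = VisitMatrix(pd.DataFrame([[5.0]], index=["C106"],
                                      columns=["Vulpes_vulpes"]))
    species = pd.DataFrame({"species_id": ["Vulpes_vulpes"],
                            "feeding_rate": [7.4],
                            "undamaged_fraction": [0.97]})
    plants = pd.DataFrame({"plant_id": ["C106"], "seeds_per_cone": [5.22],
                           "seed_viability": [0.21]})
    table = estimate_dispersed_seeds(visits, species, plants)
    return float(table.matrix.iloc[0, 0])


def camera_worked_example(study_days: int = 434) -> tuple[float, float]:
    """Four camera records of a blackbird on a small plant.

    60% surface coverage -> 6.7 whole-plant visits; recorded during 20% of
    the study -> 33.3 whole-study visits.  Returns (whole_plant,
    whole_study).
    """
    coverage = coverage_fraction_for_cover(15.0)  # small plant, < 20 m2
    whole_plant = 4.0 / coverage
    records = pd.DataFrame({
        "plant_id": ["p1"], "species_id": ["Turdus_merula"],
        "n_records": [4], "recorded_days": [0.20 * study_days],
        "coverage_fraction": [coverage],
    })
    matrix = standardize_camera(records, study_days=study_days)
    whole_study = float(matrix.table.iloc[0, 0])
    return whole_plant, whole_study


def reference_contingency():
    """Chi-squared test on the observed module x stand plant counts."""
    table = reference.module_stand_counts()
    return pearson_chi_squared(table), adjusted_residuals(table)


def reference_bookkeeping() -> dict:
    """Visit totals and species shares recomputed from the reference table."""
    summary = reference.survey_summary()
    visits = reference.species_table().set_index("species_id")[
        [f"visits_{s}" for s in reference.STANDS]]
    shares = species_shares(SeedRainTable(visits.T.rename_axis(None)))
    # species_shares normalizes the pooled matrix; identical to summary shares
    summary["top3_share_pct"] = float(
        100 * shares.sort_values(ascending=False).head(3).sum())
    return summary


def verify_reference(atol: float = 0.051) -> dict:
    """Run every desk check; returns {name: (computed, expected, ok)}."""
    checks = {}
    seeds = seed_rain_worked_example()
    checks["seed_rain_worked_example"] = (round(seeds, 1), 39.3,
                                          abs(seeds - 39.3) <= atol)
    wp, ws = camera_worked_example()
    checks["camera_whole_plant"] = (round(wp, 1), 6.7, abs(wp - 6.7) <= atol)
    checks["camera_whole_study"] = (round(ws, 1), 33.3,
                                    abs(ws - 33.3) <= atol)
    chi, _ = reference_contingency()
    checks["contingency_chi2"] = (round(chi.statistic, 2), 22.12,
                                  abs(chi.statistic - 22.12) <= 0.005)
    checks["contingency_df"] = (chi.df, 4, chi.df == 4)
    book = reference_bookkeeping()
    checks["total_visits"] = (book["total_visits"], 109988.0,
                              book["total_visits"] == 109988.0)
    checks["col_stand_visits"] = (book["stand_totals"]["COL"], 54810.0,
                                  book["stand_totals"]["COL"] == 54810.0)
    top = sorted(book["species_share_pct"].values(), reverse=True)[:3]
    for name, expected, got in (
            ("share_rank1_pct", 76.27, top[0]),
            ("share_rank2_pct", 11.47, top[1]),
            ("share_rank3_pct", 6.18, top[2])):
        checks[name] = (round(got, 2), expected,
                        abs(got - expected) <= 0.005)
    checks["top3_joint_share_pct"] = (round(book["top3_share_pct"]), 94,
                                      round(book["top3_share_pct"]) == 94)
    return checks
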