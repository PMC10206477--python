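"""Sampling-effort standardization of the two interaction surveys.

Cameras frame only part of a plant and run only part of the study; seed traps
sample only part of the canopy's drop zone.  Raw detection counts are
therefore scaled to whole-plant, whole-study visit estimates:

``camera estimate = records / coverage_fraction / (recorded_days/study_days)``
``scat estimate   = samples / min(1, sampled_area/canopy_area) / (active_days/study_days)``

For example, four camera records of a foraging bird on a small plant (60%
surface coverage) give 4 / 0.6 = 6.7 whole-plant visits; if that plant was
recorded during 20% of the study, the whole-study estimate is 33.3 visits.

Once both channels are in the same units they can be merged cell-wise into a
single weighted adjacency matrix (:func:`frugnet.matrix.merge_visit_matrices`).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .matrix import VisitMatrix
from .synthesize import UNIDENTIFIED

__all__ = [
    "coverage_fraction_for_cover",
    "filter_foraging",
    "standardize_camera",
    "standardize_scats",
]


def coverage_fraction_for_cover(cover: float,
                                breaks: tuple = (20.0, 40.0),
                                fractions: tuple = (0.60, 0.40, 0.20)
                                ) -> float:
    """Camera surface coverage by plant size class.

    Small plants (cover < 20 m²) have 60% of their surface in frame, medium
    plants (20–40 m² inclusive) 40%, large plants (> 40 m²) 20%.
    """
    if not np.isfinite(cover) or cover <= 0:
        raise ValueError(f"plant cover must be positive, got {cover}")
    if cover < breaks[0]:
        return fractions[0]
    if cover <= breaks[1]:
        return fractions[1]
    return fractions[2]


def filter_foraging(camera_records: pd.DataFrame) -> pd.DataFrame:
    """Behaviour filter: keep only true cone-foraging visits.

    Records of animals merely passing, perching or scent-marking carry
    ``behaviour != "foraging"`` and are discarded (in the reference survey
    this step removed ~52% of raw camera records).  Tables without a
    ``behaviour`` column are assumed pre-filtered.
    """
    if "behaviour" not in camera_records.columns:
        return camera_records
    return camera_records[camera_records["behaviour"] == "foraging"].copy()


def _empty_matrix(plants, species) -> pd.DataFrame:
    return pd.DataFrame(0.0, index=pd.Index(plants, name="plant_id"),
                        columns=pd.Index(species, name="species_id"))


def standardize_camera(records: pd.DataFrame, study_days: float,
                       plants=None, species=None) -> VisitMatrix:
    """Scale camera records to whole-plant, whole-study visit estimates.

    ``records`` needs columns plant_id, species_id, n_records,
    recorded_days, coverage_fraction (a ``behaviour`` column, if present, is
    filtered to foraging records first).  ``plants``/``species`` fix the
    row/column universe; by default the ids present in the records are used.
    Cells with no records are zero.
    """
    records = filter_foraging(records)
    if len(records):
        cov = records["coverage_fraction"].to_numpy(dtype=float)
        days = records["recorded_days"].to_numpy(dtype=float)
        if ((cov <= 0) | (cov > 1)).any():
            raise ValueError("coverage_fraction outside (0, 1]")
        if ((days <= 0) | (days > study_days)).any():
            raise ValueError("recorded_days outside (0, study_days]")
        est = records["n_records"].to_numpy(dtype=float) / cov \
            / (days / float(study_days))
        tidy = records.assign(estimate=est)
        wide = tidy.pivot_table(index="plant_id", columns="species_id",
                                values="estimate", aggfunc="sum",
                                fill_value=0.0)
    else:
        wide = pd.DataFrame(dtype=float)
    if plants is None:
        plants = list(wide.index)
    if species is None:
        species = list(wide.columns)
    out = _empty_matrix(plants, species)
    shared_p = [p for p in wide.index if p in out.index]
    shared_s = [s for s in wide.columns if s in out.columns]
    out.loc[shared_p, shared_s] = wide.loc[shared_p, shared_s]
    return VisitMatrix(out)


def standardize_scats(records: pd.DataFrame, study_days: float,
                      plants=None, species=None) -> VisitMatrix:
    """Scale identified scat/barcoding samples to whole-plant visit estimates.

    Unidentified samples (species_id == ``UNIDENTIFIED``) are dropped before
    scaling, as barcoding failures carry no species information.  The area
    fraction ``sampled_area / canopy_area`` is capped at 1 (a trap cannot
    oversample the canopy).
    """
    records = records[records["species_id"] != UNIDENTIFIED]
    if len(records):
        canopy = records["canopy_area"].to_numpy(dtype=float)
        area = records["sampled_area"].to_numpy(dtype=float)
        days = records["active_days"].to_numpy(dtype=float)
        if (canopy <= 0).any():
            raise ValueError("canopy_area must be positive")
        if (area <= 0).any():
            raise ValueError("sampled_area must be positive")
        if ((days <= 0) | (days > study_days)).any():
            raise ValueError("active_days outside (0, study_days]")
        frac = np.minimum(1.0, area / canopy)
        est = records["n_samples"].to_numpy(dtype=float) / frac \
            / (days / float(study_days))
        tidy = records.assign(estimate=est)
        wide = tidy.pivot_table(index="plant_id", columns="species_id",
                                values="estimate", aggfunc="sum",
                                fill_value=0.0)
    else:
        wide = pd.DataFrame(dtype=float)
    if plants is None:
        plants = list(wide.index)
    if species is None:
        species = list(wide.columns)
    out = _empty_matrix(plants, species)
    shared_p = [p for p in wide.index if p in out.index]
    shared_s = [s for s in wide.columns if s in out.columns]
    out.loc[shared_p, shared_s] = wide.loc[shared_p, shared_s]
    return VisitMatrix(out)
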