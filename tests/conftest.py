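import numpy as np
import pandas as pd
import pytest

from frugnet import (StudyConfig, VisitMatrix, merge_visit_matrices,
                     simulate_study, standardize_camera, standardize_scats)


def run_standardization(cfg, plants, camera, scats):
    """Standardize both survey channels and merge them."""
    plant_ids = plants["plant_id"].tolist()
    species_ids = cfg.species["species_id"].tolist()
    cam = standardize_camera(camera, cfg.study_days, plants=plant_ids,
                             species=species_ids)
    sca = standardize_scats(scats, cfg.study_days, plants=plant_ids,
                            species=species_ids)
    return merge_visit_matrices(cam, sca)


@pytest.fixture(scope="session")
def default_study():
    """One realistic simulated study (reference design), shared read-only."""
    cfg = StudyConfig.default(rng_seed=11)
    plants, true, camera, scats = simulate_study(cfg)
    matrix = run_standardization(cfg, plants, camera, scats)
    return {"config": cfg, "plants": plants, "true": true,
            "camera": camera, "scats": scats, "matrix": matrix}


@pytest.fixture(scope="session")
def modular_study():
    """A planted three-module study for recovery checks."""
    cfg = StudyConfig.strong_modular(rng_seed=23)
    plants, true, camera, scats = simulate_study(cfg)
    matrix = run_standardization(cfg, plants, camera, scats)
    return {"config": cfg, "plants": plants, "true": true,
            "camera": camera, "scats": scats, "matrix": matrix}


def random_visit_matrix(rng, max_dim=4, integer=True):
    """Small random matrix with every row and column connected."""
    r, c = rng.integers(2, max_dim + 1, size=2)
    A = rng.integers(0, 5, size=(r, c)).astype(float)
    if not integer:
        A *= rng.uniform(0.5, 1.5, size=A.shape)
    bad = (A.sum(axis=1) == 0) | np.array([False] * r)
    A[bad, 0] += 1
    A[:, A.sum(axis=0) == 0] += 1
    return VisitMatrix(pd.DataFrame(
        A, index=[f"p{i}" for i in range(r)],
        columns=[f"s{j}" for j in range(c)]))
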