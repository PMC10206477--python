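"""Generator behaviour: determinism, design constants, thinning expectations."""

import numpy as np
import pandas as pd
import pytest

from frugnet import (ConfigError, StudyConfig, generate_plants,
                     simulate_camera_survey, simulate_scat_survey,
                     simulate_true_visits)
from frugnet.config import NUTRITION_TRAITS
from frugnet.synthesize import UNIDENTIFIED


def test_plant_table_matches_study_design():
    plants = generate_plants(StudyConfig.default(rng_seed=0))
    assert len(plants) == 105
    assert plants.groupby("stand").size().eq(35).all()
    assert (plants["cover"] > 0).all()
    assert plants["seed_viability"].between(0, 1).all()
    assert plants["seeds_per_cone"].between(1, 10).all()
    # pulp chemistry is all-or-none per plant
    n_nut = plants[list(NUTRITION_TRAITS)].notna().sum(axis=1)
    assert set(n_nut.unique()) <= {0, len(NUTRITION_TRAITS)}
    assert (n_nut > 0).sum() == 82


def test_trait_gradient_follows_configured_stand_means():
    cfg = StudyConfig.default(rng_seed=3)
    plants = generate_plants(cfg)
    means = plants.groupby("stand")["cone_diameter"].mean()
    assert means["MAR"] < means["OJI"] < means["COL"]
    dens = plants.groupby("stand")["neigh_density"].mean()
    assert dens["COL"] < dens["MAR"]


def test_zero_spread_collapses_to_stand_means():
    cfg = StudyConfig.default(rng_seed=0)
    cfg.trait_sds = {t: tuple(0.0 for _ in v)
                     for t, v in cfg.trait_sds.items()}
    plants = generate_plants(cfg)
    for s_idx, stand in enumerate(cfg.stand_labels):
        sub = plants[plants["stand"] == stand]
        assert np.allclose(sub["cone_diameter"],
                           cfg.trait_means["cone_diameter"][s_idx])
        assert np.allclose(sub["crop_size"],
                           cfg.trait_means["crop_size"][s_idx])


def test_same_seed_reproduces_everything():
    cfg = StudyConfig.default(rng_seed=17)
    a = generate_plants(cfg)
    b = generate_plants(cfg)
    pd.testing.assert_frame_equal(a, b)
    ta = simulate_true_visits(a, cfg)
    tb = simulate_true_visits(b, cfg)
    pd.testing.assert_frame_equal(ta.matrix, tb.matrix)
    pd.testing.assert_frame_equal(simulate_camera_survey(ta, a, cfg),
                                  simulate_camera_survey(tb, b, cfg))
    pd.testing.assert_frame_equal(simulate_scat_survey(ta, a, cfg),
                                  simulate_scat_survey(tb, b, cfg))


def test_invalid_config_rejected():
    cfg = StudyConfig.default()
    cfg.trait_sds = dict(cfg.trait_sds)
    cfg.trait_sds["cover"] = (-1.0, 1.0, 1.0)
    with pytest.raises(ConfigError):
        generate_plants(cfg)
    cfg2 = StudyConfig.default()
    cfg2.id_success = 1.2
    with pytest.raises(ConfigError):
        cfg2.validate()


def test_zero_intensity_species_never_visits():
    cfg = StudyConfig.default(rng_seed=5)
    cfg.species = cfg.species.copy()
    cfg.species.loc[cfg.species["species_id"] == "Vulpes_vulpes",
                    "intensity_MAR"] = 0.0
    plants = generate_plants(cfg)
    true = simulate_true_visits(plants, cfg)
    mar = plants.loc[plants["stand"] == "MAR", "plant_id"]
    assert (true.matrix.loc[mar, "Vulpes_vulpes"] == 0).all()


def test_poisson_limit_matches_stated_mean():
    """dispersion -> inf gives Poisson counts with the configured mean."""
    cfg = StudyConfig.default(rng_seed=9)
    cfg.dispersion = np.inf
    cfg.attract_crop_coef = cfg.attract_cone_coef = 0.0
    cfg.plants_per_stand = 100
    target = 10.0
    for col in [c for c in cfg.species.columns if c.startswith("intensity")]:
        cfg.species[col] = target
    draws = []
    for seed in range(34):  # ~1.2e4 replicate cells
        cfg.rng_seed = seed
        plants = generate_plants(cfg)
        draws.append(simulate_true_visits(plants, cfg).matrix.to_numpy())
    draws = np.concatenate([d.ravel() for d in draws])
    se = draws.std(ddof=1) / np.sqrt(len(draws))
    assert abs(draws.mean() - target) < 3 * se


def test_camera_thinning_expectation():
    """Detection = Binomial(true, coverage * time fraction): with thinning
    probability 0.12 and ~33.3 true visits, mean detections are ~4."""
    rng = np.random.default_rng(0)
    p = 0.60 * 0.20
    true_visits = 33
    draws = rng.binomial(true_visits, p, size=10_000)
    se = draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(draws.mean() - true_visits * p) < 3 * se
    # and the generator's camera channel applies exactly that thinning:
    cfg = StudyConfig.default(rng_seed=4)
    plants = generate_plants(cfg)
    true = simulate_true_visits(plants, cfg)
    cam = simulate_camera_survey(true, plants, cfg)
    forage = cam[cam["behaviour"] == "foraging"]
    detected = forage.groupby("plant_id")["n_records"].sum()
    latent = true.matrix.sum(axis=1).loc[detected.index]
    assert (detected <= latent).all()


def test_behaviour_filter_load_matches_design():
    """~52% of raw camera records are non-foraging under the default mix."""
    cfg = StudyConfig.default(rng_seed=21)
    plants = generate_plants(cfg)
    true = simulate_true_visits(plants, cfg)
    cam = simulate_camera_survey(true, plants, cfg)
    by_behaviour = cam.groupby("behaviour")["n_records"].sum()
    frac_foraging = by_behaviour["foraging"] / by_behaviour.sum()
    assert abs(frac_foraging - cfg.foraging_fraction) < 0.02


def test_barcoding_failure_rate():
    """With 92.6% identification success, ~74 of 1000 samples lack an id."""
    cfg = StudyConfig.default(rng_seed=2)
    plants = generate_plants(cfg)
    true = simulate_true_visits(plants, cfg)
    scats = simulate_scat_survey(true, plants, cfg)
    n_unid = scats.loc[scats["species_id"] == UNIDENTIFIED,
                       "n_samples"].sum()
    n_total = scats["n_samples"].sum()
    p_fail = 1 - cfg.id_success
    se = np.sqrt(n_total * p_fail * (1 - p_fail))
    assert abs(n_unid - n_total * p_fail) < 3 * se


def test_perfect_identification_leaves_nothing_unidentified():
    cfg = StudyConfig.default(rng_seed=2)
    cfg.id_success = 1.0
    plants = generate_plants(cfg)
    true = simulate_true_visits(plants, cfg)
    scats = simulate_scat_survey(true, plants, cfg)
    assert UNIDENTIFIED not in set(scats["species_id"])


def test_block_intensities_plant_modules_equal_stands():
    cfg = StudyConfig.strong_modular(rng_seed=0)
    plants = generate_plants(cfg)
    true = simulate_true_visits(plants, cfg)
    by_stand = plants.set_index("plant_id")["stand"]
    module_of_stand = {"COL": "A", "OJI": "B", "MAR": "C"}
    expected = by_stand.map(module_of_stand)
    assert (true.plant_modules.loc[expected.index] == expected).all()
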