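"""Synthetic survey generator with known ground truth.

Simulates the full observation chain of an individual-based frugivory study:

1. plants with stand-structured traits (:func:`generate_plants`);
2. a latent whole-season visit matrix — each species visits each plant a
   negative-binomially distributed number of times around a mean set by the
   species' stand-specific intensity and the plant's attractiveness
   (:func:`simulate_true_visits`);
3. a camera-trap survey that binomially thins the latent visits by camera
   coverage and recording time and adds non-foraging records that a
   behaviour filter must remove (:func:`simulate_camera_survey`);
4. a seed-trap / DNA-barcoding survey that thins by sampled area and active
   days and loses a fraction of samples to failed identification
   (:func:`simulate_scat_survey`).

Because the planted module structure and all generating parameters are known,
every downstream stage (standardization, modularity, trait discrimination,
seed-rain estimation) can be tested for recovery of the truth.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .config import (StudyConfig, ConfigError, TRAIT_BOUNDS, NUTRITION_TRAITS)

__all__ = [
    "TrueVisits",
    "generate_plants",
    "simulate_true_visits",
    "simulate_camera_survey",
    "simulate_scat_survey",
    "simulate_study",
    "write_study",
]

UNIDENTIFIED = "UNIDENTIFIED"


@dataclass
class TrueVisits:
    """Latent whole-study visit matrix with planted ground truth.

    ``matrix`` is plants x species (integer visit counts); the module labels
    record the planted partition implied by the species-affinity design.
    """

    matrix: pd.DataFrame
    plant_modules: pd.Series
    species_modules: pd.Series


def _rng(config: StudyConfig, salt: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([config.rng_seed, salt]))


def _clip(trait: str, values: np.ndarray) -> np.ndarray:
    lo, hi = TRAIT_BOUNDS.get(trait, (None, None))
    return np.clip(values, lo, hi)


def generate_plants(config: StudyConfig) -> pd.DataFrame:
    """Draw the focal-plant table: ``plants_per_stand`` plants per stand.

    Traits follow per-stand normal distributions (crop size: moment-matched
    lognormal, reflecting right-skewed fecundity) truncated to plausibility
    bounds.  A random subset of plants (``nutrition_fraction``) carries the
    four pulp-chemistry traits; the rest have them missing, mimicking
    incomplete lab assays.  Deterministic given ``rng_seed``.
    """
    config.validate()
    rng = _rng(config, 1)
    rows = []
    for s_idx, stand in enumerate(config.stand_labels):
        n = config.plants_per_stand
        rec = {
            "plant_id": [f"{stand}_{i + 1:03d}" for i in range(n)],
            "stand": [stand] * n,
        }
        for trait, means in config.trait_means.items():
            mu = float(np.atleast_1d(means)[s_idx])
            sd = float(np.atleast_1d(config.trait_sds[trait])[s_idx])
            if trait == "crop_size" and sd > 0:
                # lognormal matched to (mu, sd)
                sigma2 = np.log1p((sd / mu) ** 2)
                draw = rng.lognormal(np.log(mu) - sigma2 / 2.0,
                                     np.sqrt(sigma2), size=n)
            else:
                draw = rng.normal(mu, sd, size=n)
            rec[trait] = _clip(trait, draw)
        rows.append(pd.DataFrame(rec))
    plants = pd.concat(rows, ignore_index=True)
    # pulp chemistry measured for a subset of plants only, all-or-none per plant
    n_total = len(plants)
    n_with = int(round(config.nutrition_fraction * n_total))
    rng2 = _rng(config, 2)
    with_nutrition = np.zeros(n_total, dtype=bool)
    with_nutrition[rng2.choice(n_total, size=n_with, replace=False)] = True
    for trait in NUTRITION_TRAITS:
        plants.loc[~with_nutrition, trait] = np.nan
    return plants


def _intensity_matrix(plants: pd.DataFrame, config: StudyConfig) -> np.ndarray:
    """Expected visits per (plant, species) before attractiveness scaling."""
    icols = {s: f"intensity_{s}" for s in config.stand_labels}
    out = np.zeros((len(plants), len(config.species)))
    for j, (_, sp) in enumerate(config.species.iterrows()):
        per_stand = {s: float(sp[c]) for s, c in icols.items()}
        out[:, j] = plants["stand"].map(per_stand).to_numpy()
    return out


def _attractiveness(plants: pd.DataFrame, config: StudyConfig) -> np.ndarray:
    """Log-linear plant attractiveness, mean-one within each stand.

    More fecund plants with larger cones receive proportionally more visits;
    coefficients act on globally standardized log crop size and cone
    diameter.  Normalizing to mean one per stand keeps each stand's mean
    visitation at the configured intensity.
    """
    log_crop = np.log(plants["crop_size"].to_numpy(dtype=float))
    cone = plants["cone_diameter"].to_numpy(dtype=float)

    def z(x):
        sd = x.std(ddof=0)
        return (x - x.mean()) / sd if sd > 0 else np.zeros_like(x)

    raw = np.exp(config.attract_crop_coef * z(log_crop)
                 + config.attract_cone_coef * z(cone))
    attract = raw.copy()
    for stand in config.stand_labels:
        mask = (plants["stand"] == stand).to_numpy()
        attract[mask] = raw[mask] / raw[mask].mean()
    return attract


def planted_modules(plants: pd.DataFrame,
                    config: StudyConfig) -> tuple[pd.Series, pd.Series]:
    """Ground-truth module labels implied by the species-affinity design.

    Species carry their configured module affinity; a plant belongs to the
    module whose member species jointly contribute the largest expected
    visitation in the plant's stand.
    """
    species_modules = pd.Series(config.species["module"].to_numpy(),
                                index=config.species["species_id"].to_numpy())
    modules = sorted(species_modules.unique())
    stand_module = {}
    for stand in config.stand_labels:
        best, best_val = None, -1.0
        for m in modules:
            members = config.species["module"] == m
            val = config.species.loc[members, f"intensity_{stand}"].sum()
            if val > best_val:
                best, best_val = m, float(val)
        stand_module[stand] = best
    plant_modules = pd.Series(plants["stand"].map(stand_module).to_numpy(),
                              index=plants["plant_id"].to_numpy())
    return plant_modules, species_modules


def simulate_true_visits(plants: pd.DataFrame,
                         config: StudyConfig) -> TrueVisits:
    """Draw the latent whole-study visit counts.

    Cell (p, f) is negative binomial with mean = stand intensity of species f
    times plant p's attractiveness, and overdispersion ``config.dispersion``
    (size parameter; ``inf`` gives the Poisson limit).
    """
    config.validate()
    rng = _rng(config, 3)
    mean = _intensity_matrix(plants, config) * \
        _attractiveness(plants, config)[:, None]
    kappa = config.dispersion
    counts = np.zeros_like(mean, dtype=np.int64)
    pos = mean > 0
    if np.isinf(kappa):
        counts[pos] = rng.poisson(mean[pos])
    else:
        p = kappa / (kappa + mean[pos])
        counts[pos] = rng.negative_binomial(kappa, p)
    matrix = pd.DataFrame(counts,
                          index=plants["plant_id"].to_numpy(),
                          columns=config.species["species_id"].to_numpy())
    plant_mod, species_mod = planted_modules(plants, config)
    return TrueVisits(matrix, plant_mod, species_mod)


def simulate_camera_survey(true_visits: TrueVisits, plants: pd.DataFrame,
                           config: StudyConfig) -> pd.DataFrame:
    """Subsample the latent visits the way rotating camera traps would.

    Each plant is recorded for ``recorded_days`` (normal around the camera
    schedule mean, truncated to (1, study_days]) and the camera frames a
    fixed fraction of the plant surface set by its cover size class.  Each
    latent visit is detected independently with probability
    ``coverage * recorded_days / study_days``.  Non-foraging records (passive
    perching, transit) are generated on top at the rate implied by
    ``foraging_fraction`` and flagged in the ``behaviour`` column; the
    standardization stage must filter them out.

    Returns a tidy record table with columns plant_id, species_id, behaviour,
    n_records, recorded_days, coverage_fraction.
    """
    from .standardize import coverage_fraction_for_cover

    config.validate()
    rng = _rng(config, 4)
    days = rng.normal(config.camera_days_mean, config.camera_days_sd,
                      size=len(plants))
    days = np.clip(days, 1.0, float(config.study_days))
    if (days > config.study_days).any():
        raise ConfigError("recorded_days exceeds study_days")
    ff = config.foraging_fraction
    other_rate = (1.0 - ff) / ff if ff > 0 else 0.0
    rows = []
    for i, plant in plants.reset_index(drop=True).iterrows():
        coverage = coverage_fraction_for_cover(
            float(plant["cover"]),
            breaks=config.camera_coverage_breaks,
            fractions=config.camera_coverage_fracs)
        p_detect = coverage * days[i] / config.study_days
        truth = true_visits.matrix.loc[plant["plant_id"]]
        for species_id, n_true in truth.items():
            n_forage = int(rng.binomial(int(n_true), p_detect))
            n_other = int(rng.poisson(n_forage * other_rate))
            for behaviour, n in (("foraging", n_forage), ("other", n_other)):
                if n > 0:
                    rows.append((plant["plant_id"], species_id, behaviour, n,
                                 float(days[i]), coverage))
    return pd.DataFrame(rows, columns=[
        "plant_id", "species_id", "behaviour", "n_records",
        "recorded_days", "coverage_fraction"])


def simulate_scat_survey(true_visits: TrueVisits, plants: pd.DataFrame,
                         config: StudyConfig) -> pd.DataFrame:
    """Subsample the latent visits via seed traps and DNA barcoding.

    The trap samples ``sampled_area`` m² beneath a canopy of ``canopy_area``
    (= plant cover) m² for ``active_days`` of the study; each latent visit
    drops a detectable sample into the trap with probability
    ``min(1, sampled_area/canopy_area) * active_days / study_days``.  The
    largest plants (cover above the upper camera size-class break) get a
    second tray, doubling the sampled area.  Each detection is independently
    unidentifiable with probability ``1 - id_success``; unidentified samples
    are pooled per plant under species id ``UNIDENTIFIED``.

    Returns a tidy table with columns plant_id, species_id, n_samples,
    sampled_area, canopy_area, active_days.
    """
    config.validate()
    rng = _rng(config, 5)
    n = len(plants)
    area = np.clip(rng.normal(config.trap_area_mean, config.trap_area_sd,
                              size=n), 0.05, None)
    large = plants["cover"].to_numpy(dtype=float) > \
        config.camera_coverage_breaks[-1]
    area = np.where(large, 2.0 * area, area)
    active = np.clip(rng.normal(config.trap_days_mean, config.trap_days_sd,
                                size=n), 1.0, float(config.study_days))
    rows = []
    for i, plant in plants.reset_index(drop=True).iterrows():
        canopy = float(plant["cover"])
        p_detect = min(1.0, area[i] / canopy) * active[i] / config.study_days
        truth = true_visits.matrix.loc[plant["plant_id"]]
        unidentified = 0
        for species_id, n_true in truth.items():
            detected = int(rng.binomial(int(n_true), p_detect))
            identified = int(rng.binomial(detected, config.id_success))
            unidentified += detected - identified
            if identified > 0:
                rows.append((plant["plant_id"], species_id, identified,
                             float(area[i]), canopy, float(active[i])))
        if unidentified > 0:
            rows.append((plant["plant_id"], UNIDENTIFIED, unidentified,
                         float(area[i]), canopy, float(active[i])))
    return pd.DataFrame(rows, columns=[
        "plant_id", "species_id", "n_samples", "sampled_area",
        "canopy_area", "active_days"])


def simulate_study(config: StudyConfig):
    """Run the whole generative chain; returns (plants, true, camera, scats)."""
    plants = generate_plants(config)
    true = simulate_true_visits(plants, config)
    camera = simulate_camera_survey(true, plants, config)
    scats = simulate_scat_survey(true, plants, config)
    return plants, true, camera, scats


def write_study(config: StudyConfig, outdir) -> dict:
    """Generate a study and write the four raw CSVs plus ground truth.

    Writes plants.csv, species.csv, camera_records.csv, scat_records.csv and
    ground_truth.json (planted module labels and key generating parameters)
    into ``outdir``; returns the paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    plants, true, camera, scats = simulate_study(config)
    paths = {
        "plants": outdir / "plants.csv",
        "species": outdir / "species.csv",
        "camera_records": outdir / "camera_records.csv",
        "scat_records": outdir / "scat_records.csv",
        "ground_truth": outdir / "ground_truth.json",
    }
    plants.to_csv(paths["plants"], index=False)
    config.species.to_csv(paths["species"], index=False)
    camera.to_csv(paths["camera_records"], index=False)
    scats.to_csv(paths["scat_records"], index=False)
    truth = {
        "plant_modules": true.plant_modules.to_dict(),
        "species_modules": true.species_modules.to_dict(),
        "rng_seed": config.rng_seed,
        "foraging_fraction": config.foraging_fraction,
        "id_success": config.id_success,
        "true_total_visits": int(true.matrix.to_numpy().sum()),
    }
    with open(paths["ground_truth"], "w") as fh:
        json.dump(truth, fh, indent=2)
    return paths
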