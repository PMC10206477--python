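"""End-to-end orchestration: read (or synthesize) the four raw tables, run
standardization -> merging -> modularity -> null significance -> node roles ->
module composition -> trait LDA -> seed rain -> regressions, and persist every
artifact as CSV/JSON."""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .config import StudyConfig
from .matrix import VisitMatrix, merge_visit_matrices
from .standardize import standardize_camera, standardize_scats
from .network import (dirt_lpawb_plus, vaznull_ensemble, node_roles,
                      node_strength)
from .composition import (stand_module_table, pearson_chi_squared,
                          adjusted_residuals)
from .discriminant import vif_prune, greedy_wilks, lda_fit_classify
from .seedrain import (estimate_dispersed_seeds, species_shares,
                       bootstrap_species_totals, contribution_regression,
                       group_anova_tukey, stand_zscores, plants_to_reach,
                       loglog_regression)
from .synthesize import write_study

__all__ = ["PipelineConfig", "ValidationError", "PipelineStageError",
           "read_tables", "run_all"]

#: LDA candidate variables (morphology, fecundity, cones, neighbourhood)
TRAIT_COLUMNS = ["cover", "height", "crop_size", "cone_diameter",
                 "cone_length", "cone_mass", "seeds_per_cone",
                 "seed_viability", "neigh_density", "neigh_fecundity"]


class ValidationError(ValueError):
    """Input table violates the documented schema."""


class PipelineStageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class PipelineConfig:
    """Everything needed to run the analysis end to end.

    Either ``data_dir`` points at the four raw CSVs (plants.csv, species.csv,
    camera_records.csv, scat_records.csv) or ``synthesis`` holds a
    :class:`StudyConfig` from which they are generated first.
    """

    output_dir: str = "frugnet_output"
    data_dir: str | None = None
    synthesis: StudyConfig | None = None
    study_days: int = 434
    n_null: int = 100
    modularity_steps: int = 1000
    modularity_tolerance: float = 1e-10
    modularity_restarts: int = 20
    vif_threshold: float = 3.0
    entry_alpha: float = 0.2
    bootstrap_reps: int = 1000
    rng_seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh)
        synth = payload.pop("synthesis", None)
        cfg = cls(**payload)
        if synth is not None:
            if isinstance(synth, dict) and synth.get("preset") == \
                    "strong_modular":
                cfg.synthesis = StudyConfig.strong_modular(
                    rng_seed=synth.get("rng_seed", cfg.rng_seed))
            else:
                synth = synth if isinstance(synth, dict) else {}
                synth.setdefault("rng_seed", cfg.rng_seed)
                cfg.synthesis = StudyConfig(**synth).validate()
        return cfg


# ----------------------------------------------------------------------
# Schema validation
# ----------------------------------------------------------------------

def _check(df: pd.DataFrame, name: str, required: dict,
           problems: list) -> None:
    for col, rule in required.items():
        if col not in df.columns:
            problems.append(f"{name}: missing column {col!r}")
            continue
        if rule is None:
            continue
        bad = df.index[~df[col].map(rule).fillna(False)].tolist()
        if bad:
            problems.append(
                f"{name}: column {col!r} out of range at rows {bad[:5]}")


def read_tables(data_dir, study_days: int = 434):
    """Read and validate the four raw CSVs.

    Returns (plants, species, camera_records, scat_records).  All schema
    violations are collected and reported together; unrecognized extra
    columns are preserved but ignored.
    """
    data_dir = Path(data_dir)
    try:
        plants = pd.read_csv(data_dir / "plants.csv")
        species = pd.read_csv(data_dir / "species.csv")
        camera = pd.read_csv(data_dir / "camera_records.csv")
        scats = pd.read_csv(data_dir / "scat_records.csv")
    except FileNotFoundError as exc:
        raise ValidationError(str(exc)) from exc
    problems: list[str] = []
    _check(plants, "plants.csv", {
        "plant_id": None, "stand": None,
        "cover": lambda v: v > 0,
        "seeds_per_cone": lambda v: 1 <= v <= 10,
        "seed_viability": lambda v: 0 <= v <= 1,
    }, problems)
    if "plant_id" in plants and plants["plant_id"].duplicated().any():
        problems.append("plants.csv: duplicate plant_id")
    _check(species, "species.csv", {
        "species_id": None, "functional_group": None,
        "feeding_rate": lambda v: v > 0,
        "undamaged_fraction": lambda v: 0 <= v <= 1,
    }, problems)
    if "species_id" in species and species["species_id"].duplicated().any():
        problems.append("species.csv: duplicate species_id")
    if len(camera):
        _check(camera, "camera_records.csv", {
            "plant_id": None, "species_id": None,
            "n_records": lambda v: v >= 0,
            "recorded_days": lambda v: 0 < v <= study_days,
            "coverage_fraction": lambda v: 0 < v <= 1,
        }, problems)
    if len(scats):
        _check(scats, "scat_records.csv", {
            "plant_id": None, "species_id": None,
            "n_samples": lambda v: v >= 0,
            "sampled_area": lambda v: v > 0,
            "canopy_area": lambda v: v > 0,
            "active_days": lambda v: 0 < v <= study_days,
        }, problems)
    if problems:
        raise ValidationError("; ".join(problems))
    return plants, species, camera, scats


# ----------------------------------------------------------------------
# The full analysis
# ----------------------------------------------------------------------

def _seed(base: int, salt: int) -> int:
    return int(np.random.SeedSequence([base, salt]).generate_state(1)[0]
               % (2 ** 31))


def run_all(config: PipelineConfig) -> dict:
    """Execute the complete analysis; returns the result bundle.

    Fully deterministic given ``config.rng_seed`` (per-stage seeds are
    derived from it).  Artifacts are written under ``config.output_dir``;
    stage failures raise :class:`PipelineStageError` naming the stage, with
    artifacts of completed stages already on disk.
    """
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    results: dict = {}
    stage = "inputs"
    try:
        if config.synthesis is not None:
            data_dir = out / "synthetic_data"
            write_study(config.synthesis, data_dir)
        elif config.data_dir is not None:
            data_dir = Path(config.data_dir)
        else:
            raise ValidationError("config needs data_dir or synthesis")
        plants, species, camera, scats = read_tables(data_dir,
                                                     config.study_days)
        plant_ids = plants["plant_id"].tolist()
        species_ids = species["species_id"].tolist()

        stage = "standardize"
        cam_matrix = standardize_camera(camera, config.study_days,
                                        plants=plant_ids,
                                        species=species_ids)
        scat_matrix = standardize_scats(scats, config.study_days,
                                        plants=plant_ids,
                                        species=species_ids)
        matrix = merge_visit_matrices(cam_matrix, scat_matrix)
        # species or plants without a single detection carry no network
        # information and are dropped (an isolated node breaks the null
        # model); downstream per-plant analyses use the networked plants
        tab = matrix.table
        tab = tab.loc[tab.sum(axis=1) > 0, tab.columns[tab.sum(axis=0) > 0]]
        matrix = VisitMatrix(tab)
        n_dropped = len(plant_ids) - len(matrix.plants)
        if n_dropped:
            warnings.warn(f"{n_dropped} plant(s) without any detected "
                          "visit excluded from the network")
            plants = plants[plants["plant_id"].isin(matrix.plants)]
        matrix.to_csv(out / "visit_matrix.csv")
        results["matrix"] = matrix

        stage = "modularity"
        partition = dirt_lpawb_plus(
            matrix, n_restarts=config.modularity_restarts,
            rng_seed=_seed(config.rng_seed, 11),
            max_steps=config.modularity_steps,
            tolerance=config.modularity_tolerance)
        results["partition"] = partition
        modules = pd.concat([
            partition.row_modules.rename("module").to_frame()
            .assign(side="plant"),
            partition.col_modules.rename("module").to_frame()
            .assign(side="species")])
        modules.rename_axis("node").to_csv(out / "modules.csv")

        stage = "null_model"
        ensemble = vaznull_ensemble(
            matrix, n_null=config.n_null,
            rng_seed=_seed(config.rng_seed, 12),
            n_restarts=max(2, config.modularity_restarts // 5),
            max_steps=config.modularity_steps,
            tolerance=config.modularity_tolerance)
        results["null_ensemble"] = ensemble
        with open(out / "qvalues.json", "w") as fh:
            json.dump({"Q_obs": ensemble.q_obs, "z": ensemble.z,
                       "p_normal": ensemble.p_normal,
                       "p_empirical": ensemble.p_empirical,
                       "null_Q": ensemble.q_null.tolist()}, fh, indent=2)

        stage = "node_roles"
        roles = node_roles(matrix, partition, weighted=True)
        roles.to_csv(out / "roles.csv")
        results["roles"] = roles

        stage = "module_composition"
        table = stand_module_table(partition, plants)
        chi = pearson_chi_squared(table)
        residuals = adjusted_residuals(table)
        table.to_csv(out / "contingency.csv")
        with open(out / "chisq.json", "w") as fh:
            json.dump({"X2": chi.statistic, "df": chi.df, "p": chi.p},
                      fh, indent=2)
        results["contingency"] = table
        results["chi_squared"] = chi
        results["residuals"] = residuals

        stage = "trait_discrimination"
        traits = plants.set_index("plant_id")[TRAIT_COLUMNS].dropna()
        groups = partition.row_modules.loc[traits.index]
        vif = vif_prune(traits, threshold=config.vif_threshold)
        selection = greedy_wilks(traits[vif.retained], groups,
                                 entry_alpha=config.entry_alpha)
        lda_vars = selection.selected or vif.retained
        lda = lda_fit_classify(traits[lda_vars], groups)
        results["vif"] = vif
        results["wilks"] = selection
        results["lda"] = lda
        with open(out / "lda_report.json", "w") as fh:
            json.dump({
                "vif_rounds": [{k: float(v) for k, v in r.items()}
                               for r in vif.rounds],
                "vif_retained": vif.retained,
                "wilks_selected": selection.selected,
                "wilks_lambda": selection.lambdas,
                "wilks_p": selection.p_values,
                "confusion": lda.confusion.to_dict(),
                "accuracy": lda.accuracy,
            }, fh, indent=2)

        stage = "seed_rain"
        seed_table = estimate_dispersed_seeds(matrix, species, plants)
        seed_table.matrix.to_csv(out / "seed_rain.csv")
        shares = species_shares(seed_table)
        boot = bootstrap_species_totals(seed_table,
                                        n_boot=config.bootstrap_reps,
                                        rng_seed=_seed(config.rng_seed, 13))
        results["seed_rain"] = seed_table
        results["species_shares"] = shares
        results["species_totals"] = boot

        stage = "contribution_models"
        focal = "Turdus_philomelos" if "Turdus_philomelos" in \
            matrix.species else matrix.species[0]
        regression = contribution_regression(seed_table, matrix, plants,
                                             species, focal_species=focal)
        contrib = seed_table.plant_totals
        module_of = plants["plant_id"].map(partition.row_modules)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # singleton modules possible
            anova_module = group_anova_tukey(
                contrib.loc[plants["plant_id"]],
                module_of.set_axis(plants["plant_id"]))
        anova_stand = group_anova_tukey(
            contrib.loc[plants["plant_id"]],
            plants.set_index("plant_id")["stand"])
        ranking = stand_zscores(seed_table, plants)
        ranking.to_csv(out / "ranking.csv", index=False)
        strength = node_strength(matrix, side="plants")
        cover = plants.set_index("plant_id")["cover"]
        reg_cover = loglog_regression(contrib, cover.loc[contrib.index])
        reg_centrality = loglog_regression(
            contrib, strength.loc[contrib.index].rename("strength")
            .clip(lower=1e-9))
        results.update({
            "regression": regression,
            "anova_module": anova_module,
            "anova_stand": anova_stand,
            "ranking": ranking,
            "plants_to_half": plants_to_reach(ranking, 0.5),
            "loglog_cover": reg_cover,
            "loglog_centrality": reg_centrality,
        })
        contrib.rename("contribution").rename_axis("plant_id") \
            .to_csv(out / "contributions.csv")
        with open(out / "regression_report.json", "w") as fh:
            json.dump({
                "terms": regression.params.to_dict(orient="index"),
                "r_squared": regression.r_squared,
                "aicc": regression.aicc,
                "lmg": regression.lmg.to_dict(),
                "anova_module": {"F": anova_module.f_statistic,
                                 "df": anova_module.df,
                                 "p": anova_module.p},
                "anova_stand": {"F": anova_stand.f_statistic,
                                "df": anova_stand.df, "p": anova_stand.p},
                "loglog_cover_r2": reg_cover.r_squared,
                "loglog_centrality_r2": reg_centrality.r_squared,
            }, fh, indent=2)

        stage = "run_log"
        with open(out / "run_log.json", "w") as fh:
            cfg = asdict(config)
            cfg["synthesis"] = (None if config.synthesis is None
                                else {"rng_seed": config.synthesis.rng_seed})
            json.dump({"frugnet_version": __version__, "config": cfg},
                      fh, indent=2, default=str)
    except PipelineStageError:
        raise
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
    return results
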