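"""End-to-end pipeline: simulate, fit, project, classify, report.

``run_pipeline`` sequences the whole analysis on a synthetic island:
generate covariates and survey data, clean occurrences, select
predictors by jackknife, fit a bootstrap ensemble of maximum-entropy
models, project to climate scenarios, derive survival limits from plot
occupancy, classify wasted dispersal per scenario, tally range change,
fit the occupancy GLM, and run the flux/front projections.  All outputs
are plain text (CSV / JSON / ASCII grids) and deterministic given the
seed: a config run twice produces byte-identical bundles.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path
from typing import Any

import numpy as np
import yaml

from . import __version__
from .dispersal import (
    estimate_survival_limit,
    scenario_sweep,
    seed_stats,
    summarize_distribution,
    value_at,
)
from .flux import FluxParams, FrontParams, front_advance, seed_flux_change
from .glm import PerfectSeparationError, fit_logistic, hosmer_lemeshow
from .grids import CovariateStack, SuitabilitySurface
from .island import (
    SeedCountModel,
    ThresholdLogisticOccupancy,
    TrueSuitabilityParams,
    apply_scenario,
    clean_occurrences,
    generate_island,
    sample_dung_piles,
    sample_occurrences,
    sample_plots,
    true_suitability,
)
from .maxent import bootstrap_ensemble, build_features, jackknife_select, predict, sample_background
from .projection import range_change
from .rasters import write_stack, write_surface
from .tables import write_occurrences, write_piles, write_plots

logger = logging.getLogger("seedwaste")

__all__ = ["default_config", "demo_config", "load_config", "run_pipeline"]


def default_config(seed: int = 0) -> dict[str, Any]:
    """Full-size study configuration on the synthetic island.

    Sample sizes follow the field study being emulated: 1,621 / 1,435
    cleaned occurrences, 36 + 28 vegetation plots on two transects at
    50 m elevation spacing, 159 + 63 dung piles, 10,000 background
    points, 100 bootstrap replicates with a 70/30 train/test split, and
    5 of the candidate predictors kept by jackknife.
    """
    return {
        "seed": seed,
        "island": {"n_rows": 160, "n_cols": 160, "peak_elevation": 860.0, "cell_size": 100.0},
        "scenarios": [
            {"id": "wet2050", "delta_temp": 1.4, "delta_precip_lowland": 40.0},
            {"id": "wet2070", "delta_temp": 1.8, "delta_precip_lowland": 70.0},
        ],
        "species": {
            "guava": {
                "true_intercept": -1.0,
                "true_coefficients": {"precip_dry": 2.2, "precip_wet": 1.2},
                "n_occurrences": 1621,
                "survival_threshold": 0.35,
                "occupancy": {"a": -1.0, "b": 4.0},
                "count_model": {"presence_prob": 0.44, "mean_seeds": 1443.0, "dispersion": 0.5},
            },
            "passionfruit": {
                "true_intercept": -0.8,
                "true_coefficients": {"temp_max": -2.0},
                "n_occurrences": 1435,
                "survival_threshold": 0.35,
                "occupancy": {"a": -1.0, "b": 4.0},
                "count_model": {"presence_prob": 0.36, "mean_seeds": 246.0, "dispersion": 0.25},
            },
        },
        "sites": {
            "LR": {"plots_range": [10.0, 400.0], "n_piles": 159},
            "CF": {"plots_range": [100.0, 400.0], "n_piles": 63},
        },
        "sdm": {
            "n_background": 10_000,
            "n_replicates": 100,
            "test_fraction": 0.3,
            "reg_multiplier": 1.0,
            "jackknife_k": 5,
        },
        "glm": {"groups": 10},
        "flux": {
            "population": 4000,
            "defecation_rate": 1.0,
            "future_scenario": "wet2070",
            "front_distance_m": 1500.0,
            "front_horizon_years": 55.0,
            "generation_time_years": 8.0,
        },
    }


def demo_config(seed: int = 0) -> dict[str, Any]:
    """Scaled-down configuration that completes in well under a minute."""
    cfg = default_config(seed)
    cfg["island"].update({"n_rows": 90, "n_cols": 90})
    cfg["species"]["guava"]["n_occurrences"] = 400
    cfg["species"]["passionfruit"]["n_occurrences"] = 350
    cfg["sdm"].update({"n_background": 3000, "n_replicates": 8, "jackknife_k": 3})
    return cfg


def load_config(path: str | Path) -> dict[str, Any]:
    with open(path) as fh:
        return yaml.safe_load(fh)


def _config_hash(config: dict[str, Any]) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True).encode()).hexdigest()


def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if dataclasses.is_dataclass(obj):
        return dataclasses.asdict(obj)
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def _write_json(path: Path, payload) -> None:
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=_json_default) + "\n")


def run_pipeline(config: dict[str, Any], out_dir: str | Path | None = None) -> dict[str, Any]:
    """Run the full analysis; return the report bundle as a dictionary.

    When ``out_dir`` is given, every stage's outputs are written there
    (rasters, survey tables, summary CSVs, JSON reports) together with a
    provenance manifest carrying the seed and a hash of the config.
    """
    import pandas as pd

    seed = int(config["seed"])
    rng_seeds = np.random.SeedSequence(seed).generate_state(16) % (2**31)
    bundle: dict[str, Any] = {"seed": seed, "config_hash": _config_hash(config)}

    # --- stage 1: island and scenarios ---------------------------------
    isl = config["island"]
    stack = generate_island(seed=int(rng_seeds[0]), **{k: isl[k] for k in isl})
    scenarios: dict[str, CovariateStack] = {"current": stack}
    for sc in config.get("scenarios", []):
        scenarios[sc["id"]] = apply_scenario(
            stack, sc.get("delta_temp", 0.0), sc.get("delta_precip_lowland", 0.0), sc["id"]
        )
    logger.info("island generated: %d land cells, %d scenarios", stack.n_land, len(scenarios) - 1)

    # --- stage 2: species truths and survey data -----------------------
    species_cfg = config["species"]
    truths: dict[str, SuitabilitySurface] = {}
    occurrences = {}
    responses = {}
    for i, (sp, sc) in enumerate(species_cfg.items()):
        params = TrueSuitabilityParams(
            intercept=sc.get("true_intercept"),
            coefficients=sc.get("true_coefficients", {}),
            opt_elevation=sc.get("true_opt_elevation"),
            breadth=sc.get("true_breadth"),
        )
        truths[sp] = true_suitability(stack, params)
        occ = sample_occurrences(truths[sp], sc["n_occurrences"], seed=int(rng_seeds[1 + i]), species=sp)
        occurrences[sp] = clean_occurrences(occ, stack)
        rule = ThresholdLogisticOccupancy(sc["survival_threshold"], **sc.get("occupancy", {}))
        responses[sp] = (truths[sp], rule)
        logger.info("%s: %d occurrences after cleaning", sp, len(occurrences[sp]))

    plots = []
    piles = []
    for j, (site, site_cfg) in enumerate(config["sites"].items()):
        plots += sample_plots(
            stack, responses, site,
            elevation_range=tuple(site_cfg["plots_range"]),
            seed=int(rng_seeds[5 + j]),
        )
        count_models = {
            sp: SeedCountModel(**species_cfg[sp]["count_model"]) for sp in species_cfg
        }
        piles += sample_dung_piles(
            stack, site, site_cfg["n_piles"], count_models, seed=int(rng_seeds[8 + j]),
        )
    logger.info("sampled %d plots, %d dung piles", len(plots), len(piles))

    # --- stage 3: SDM per species --------------------------------------
    sdm_cfg = config["sdm"]
    predictors = [k for k in stack.layers if k != "elevation"]
    background = sample_background(stack, sdm_cfg["n_background"], seed=int(rng_seeds[11]), predictors=predictors)
    surfaces: dict[str, dict[str, SuitabilitySurface]] = {}
    sdm_reports: dict[str, Any] = {}
    for i, sp in enumerate(species_cfg):
        occ = occurrences[sp]
        rows, cols = stack.cell_index(occ.x, occ.y)
        presence_cov = stack.covariates_at(predictors, rows, cols)
        jk = jackknife_select(
            presence_cov, background.covariates, predictors,
            k=sdm_cfg["jackknife_k"], reg_multiplier=sdm_cfg["reg_multiplier"],
        )
        sel = jk.selected
        feats = build_features(background.covariates, sel)
        presence_sel = {k: presence_cov[k] for k in sel}
        mean_surface, eval_report, models = bootstrap_ensemble(
            presence_sel, background, feats, stack,
            n_replicates=sdm_cfg["n_replicates"],
            test_fraction=sdm_cfg["test_fraction"],
            reg_multiplier=sdm_cfg["reg_multiplier"],
            seed=int(rng_seeds[12 + i]),
            species=sp,
        )
        mean_surface = dataclasses.replace(mean_surface, scenario_id="current")
        surfaces[sp] = {"current": mean_surface}
        for sc_id, sc_stack in scenarios.items():
            if sc_id == "current":
                continue
            proj = np.mean([predict(m, sc_stack, "logistic", species=sp).values for m in models], axis=0)
            proj[stack.mask] = 0.0
            surfaces[sp][sc_id] = SuitabilitySurface(
                values=proj, mask=stack.mask, species=sp, scenario_id=sc_id,
                output_kind="logistic", cell_size=stack.cell_size, origin=stack.origin,
            )
        sdm_reports[sp] = {
            "jackknife_gains": jk.gains,
            "selected_predictors": sel,
            "auc_train": eval_report.auc_train,
            "auc_test": eval_report.auc_test,
            "auc_label": eval_report.label,
            "n_replicates": eval_report.n_replicates,
            "surface_sd_mean": eval_report.surface_sd_mean,
        }
        logger.info("%s SDM: predictors %s, test AUC %.3f", sp, sel, eval_report.auc_test)
    bundle["sdm"] = sdm_reports

    # --- stage 4: survival limits, wasted dispersal, summaries ---------
    limits = {}
    table2_rows = []
    table1_rows = []
    stats_rows = []
    for sp in species_cfg:
        current = surfaces[sp]["current"]
        limits[sp] = estimate_survival_limit(plots, current, sp)
        reports = scenario_sweep(piles, surfaces[sp], limits[sp], sp)
        table2_rows += [r.as_dict() for r in reports]
        for site in config["sites"]:
            site_plots = [p for p in plots if p.site == site]
            site_piles = [p for p in piles if p.site == site]
            table1_rows.append(summarize_distribution(site_plots, current, sp, "plot").as_dict())
            table1_rows.append(summarize_distribution(site_piles, current, sp, "pile").as_dict())
        stats_rows.append(seed_stats(piles, sp).as_dict())
    bundle["survival_limits"] = {sp: limits[sp].limit for sp in limits}
    bundle["wasted"] = table2_rows
    bundle["distribution"] = table1_rows
    bundle["seed_stats"] = stats_rows

    # --- stage 5: range change -----------------------------------------
    rc_rows = []
    for sp in species_cfg:
        for sc_id, surf in surfaces[sp].items():
            if sc_id == "current":
                continue
            rc = range_change(surfaces[sp]["current"], surf, threshold=limits[sp].limit)
            rc_rows.append({"species": sp, "scenario_id": sc_id, **rc.as_dict()})
    bundle["range_change"] = rc_rows

    # --- stage 6: occupancy GLM ----------------------------------------
    glm_out = {}
    for sp in species_cfg:
        pres = np.array([p.presence.get(sp, 0) for p in plots])
        suit = value_at(
            surfaces[sp]["current"],
            np.array([p.x for p in plots]), np.array([p.y for p in plots]),
            allow_missing=False,
        )
        try:
            fit = fit_logistic(pres, suit)
        except PerfectSeparationError as exc:
            # a hard occupancy threshold can separate the classes exactly;
            # record the diagnostic instead of aborting the run
            glm_out[sp] = {"error": "perfect_separation", "detail": str(exc), "n": int(pres.size)}
            continue
        hl = hosmer_lemeshow(fit, g=config.get("glm", {}).get("groups", 10))
        glm_out[sp] = {
            "coef": fit.coef.tolist(),
            "se": fit.se.tolist(),
            "z": fit.z_values.tolist(),
            "p": fit.p_values.tolist(),
            "null_deviance": fit.null_deviance,
            "deviance": fit.deviance,
            "n": fit.n,
            "hosmer_lemeshow": {
                "statistic": hl.statistic, "groups": hl.groups, "df": hl.df, "p_value": hl.p_value,
            },
        }
    bundle["glm"] = glm_out

    # --- stage 7: flux and front ---------------------------------------
    flux_cfg = config["flux"]
    first_sp = next(iter(species_cfg))
    by_scenario = {r["scenario_id"]: r for r in table2_rows if r["species"] == first_sp}
    future_id = flux_cfg.get("future_scenario")
    stats0 = bundle["seed_stats"][0]
    fp = FluxParams(
        population=flux_cfg["population"],
        defecation_rate=flux_cfg["defecation_rate"],
        mean_seeds_per_pile=stats0["mean_per_pile"],
        wasted_fraction_current=by_scenario["current"]["pct_seeds_wasted"] / 100.0,
        wasted_fraction_future=by_scenario[future_id]["pct_seeds_wasted"] / 100.0 if future_id in by_scenario else 0.0,
    )
    per_day, per_year = seed_flux_change(fp)
    m_per_year, m_per_gen = front_advance(FrontParams(
        advance_distance_m=flux_cfg["front_distance_m"],
        horizon_years=flux_cfg["front_horizon_years"],
        generation_time_years=flux_cfg["generation_time_years"],
    ))
    bundle["flux_front"] = {
        "species": first_sp,
        "flux_params": dataclasses.asdict(fp),
        "seeds_per_day": per_day,
        "seeds_per_year": per_year,
        "front_m_per_year": m_per_year,
        "front_m_per_generation": m_per_gen,
    }

    # --- outputs --------------------------------------------------------
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_stack(out / "island" / "current", stack)
        for sc_id, sc_stack in scenarios.items():
            if sc_id != "current":
                write_stack(out / "island" / sc_id, sc_stack)
        for sp in species_cfg:
            sdir = out / "surfaces" / sp
            sdir.mkdir(parents=True, exist_ok=True)
            for sc_id, surf in surfaces[sp].items():
                write_surface(sdir / f"{sc_id}.asc", surf)
        write_occurrences(out / "occurrences.csv", occurrences)
        write_plots(out / "plots.csv", plots)
        write_piles(out / "piles.csv", piles)
        pd.DataFrame(table1_rows).to_csv(out / "table1_distribution.csv", index=False)
        pd.DataFrame(table2_rows).to_csv(out / "table2_wasted.csv", index=False)
        pd.DataFrame(stats_rows).to_csv(out / "seed_stats.csv", index=False)
        pd.DataFrame(rc_rows).to_csv(out / "range_change.csv", index=False)
        _write_json(out / "glm.json", glm_out)
        _write_json(out / "flux.json", bundle["flux_front"])
        _write_json(out / "sdm.json", sdm_reports)
        manifest = {
            "seed": seed,
            "config": config,
            "config_hash": bundle["config_hash"],
            "package_version": __version__,
            "counts": {
                "land_cells": stack.n_land,
                "plots": len(plots),
                "piles": len(piles),
                "occurrences": {sp: len(occurrences[sp]) for sp in occurrences},
            },
        }
        _write_json(out / "manifest.json", manifest)
    return bundle
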