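"""End-to-end pipeline runner.

Chains all stages — trait space, functional entities, alpha metrics
with the swap-null SES, VIF screening, additive models, β-diversity,
GDM fitting, deviance partitioning and the RGB turnover ordination —
writing every stage's tables to the output directory together with a
manifest recording seeds, stage status and row counts.
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .alpha import (
    NullModelConfig,
    functional_richness,
    ses_functional_richness,
    shannon_heterogeneity,
    species_richness,
    vif_screen,
)
from .beta import functional_jaccard, taxonomic_jaccard
from .entities import assign_functional_entities, site_entity_metrics
from .gam import SmoothModelSpec, fit_smooth_model, relate_metrics, spatial_only_model
from .gdm import (
    build_site_pairs,
    fit_gdm,
    partition_deviance,
    predicted_matrix,
    predictor_importance,
    rgb_ordination,
)
from .io import RunConfig, read_community, read_environment, read_traits
from .synthetic import COVER_CLASSES
from .trait_space import build_trait_space

log = logging.getLogger(__name__)

STAGES = (
    "trait_space",
    "entities",
    "alpha_metrics",
    "vif_screen",
    "additive_models",
    "beta_diversity",
    "gdm",
    "partition",
    "rgb_ordination",
)


class PipelineError(RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _stage_seeds(master: int, n: int) -> list[int]:
    # counter-based expansion so stages can be rerun in isolation
    return [int(np.random.default_rng([master, k]).integers(0, 2**31 - 1)) for k in range(n)]


def run_pipeline(cfg: RunConfig) -> dict:
    """Execute the full analysis described by ``cfg``.

    Returns the manifest dictionary (also written to
    ``out_dir/manifest.json``).  Any stage failure aborts the run,
    writing a partial manifest that names the failed stage.
    """
    logging.basicConfig(level=cfg.log_level)
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(cfg.seed, len(STAGES))
    manifest: dict = {
        "version": __version__,
        "master_seed": cfg.seed,
        "stages": {},
        "notes": [],
    }

    def finish(stage: str, t0: float, **info) -> None:
        manifest["stages"][stage] = {
            "status": "completed",
            "seconds": round(time.time() - t0, 3),
            **info,
        }
        log.info("stage %s done (%.2fs)", stage, time.time() - t0)

    def abort(stage: str, exc: Exception) -> None:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise PipelineError(stage, exc) from exc

    community = read_community(cfg.community)
    traits = read_traits(cfg.traits)
    env = read_environment(cfg.environment)
    if "heterogeneity" not in env.columns and set(COVER_CLASSES).issubset(env.columns):
        env["heterogeneity"] = shannon_heterogeneity(env[list(COVER_CLASSES)])

    # --- trait space -------------------------------------------------
    t0 = time.time()
    try:
        space = build_trait_space(traits, m_axes=max(cfg.m_axes, cfg.beta_axes))
        space.gower.to_csv(out / "gower.csv")
        space.coordinates.rename_axis("species").to_csv(out / "pcoa_coordinates.csv")
    except Exception as exc:  # noqa: BLE001 - stage boundary
        abort("trait_space", exc)
    finish("trait_space", t0, n_species=len(traits), correction=space.correction_applied)

    # --- entities ----------------------------------------------------
    t0 = time.time()
    try:
        partition = assign_functional_entities(traits)
    except Exception as exc:  # noqa: BLE001
        abort("entities", exc)
    finish("entities", t0, n_entities=partition.n_entities)

    # --- alpha metrics ----------------------------------------------
    t0 = time.time()
    try:
        metrics = site_entity_metrics(community, partition)
        metrics["FRic"] = functional_richness(community, space, m_axes=cfg.m_axes)
        ses = ses_functional_richness(
            community,
            space,
            m_axes=cfg.m_axes,
            cfg=NullModelConfig(n_randomizations=cfg.n_randomizations, seed=seeds[2]),
        )
        metrics["SES_FRic"] = ses["SES_FRic"]
        metrics = metrics.join(env, how="left")
        metrics.rename_axis("site").to_csv(out / "alpha_metrics.csv")
    except Exception as exc:  # noqa: BLE001
        abort("alpha_metrics", exc)
    finish("alpha_metrics", t0, n_sites=len(metrics))

    # --- VIF screening ----------------------------------------------
    t0 = time.time()
    predictors = [
        c
        for c in (
            "temperature",
            *COVER_CLASSES,
            "heterogeneity",
            "population",
            "elev_mean",
            "elev_sd",
        )
        if c in env.columns
    ]
    try:
        retained, trace = vif_screen(env, predictors, threshold=cfg.vif_threshold)
        trace.to_csv(out / "vif_trace.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        abort("vif_screen", exc)
    finish("vif_screen", t0, retained=retained, dropped=len(trace))

    # --- additive models --------------------------------------------
    t0 = time.time()
    try:
        rows = []
        for resp in cfg.gam_responses:
            if metrics[resp].notna().sum() <= 3 * (len(retained) + 2):
                manifest["notes"].append(
                    f"additive model for {resp!r} skipped: too few complete rows"
                )
                continue
            fit = fit_smooth_model(
                metrics, SmoothModelSpec(response=resp, predictors=retained, spatial=True)
            )
            rows.append((resp, "environment+spatial", fit.deviance_explained, fit.edf))
            sp_fit = spatial_only_model(metrics, resp)
            rows.append((resp, "spatial_only", sp_fit.deviance_explained, sp_fit.edf))
            for name, eff in fit.partial_effects.items():
                eff.to_csv(out / f"gam_{resp}_effect_{name}.csv", index=False)
        if metrics["FRic"].notna().sum() > 12:
            rel = relate_metrics(metrics, ("S", "FRic"), spatial=True)
            rows.append(("FRic~S", "metric_pair", rel.deviance_explained, rel.edf))
        pd.DataFrame(
            rows, columns=["response", "model", "deviance_explained", "edf"]
        ).to_csv(out / "gam_summary.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        abort("additive_models", exc)
    finish("additive_models", t0, n_models=len(rows))

    # --- beta diversity ---------------------------------------------
    t0 = time.time()
    richness = species_richness(community)
    if (richness < cfg.min_species).all():
        note = (
            f"all sites have fewer than {cfg.min_species} species; "
            "beta, gdm, partition and rgb stages skipped"
        )
        manifest["notes"].append(note)
        for stage in STAGES[5:]:
            manifest["stages"][stage] = {"status": "skipped", "reason": note}
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
    try:
        tax = taxonomic_jaccard(community)
        fun = functional_jaccard(
            community, space, m_axes=cfg.beta_axes, min_species=cfg.min_species
        )
        tax.matrix.to_csv(out / "beta_taxonomic.csv")
        fun.matrix.to_csv(out / "beta_functional.csv")
        tax.condensed().to_csv(out / "beta_taxonomic_pairs.csv", index=False)
        fun.condensed().to_csv(out / "beta_functional_pairs.csv", index=False)
        pd.Series(fun.excluded_sites, name="site").to_csv(
            out / "beta_excluded_sites.csv", index=False
        )
    except Exception as exc:  # noqa: BLE001
        abort("beta_diversity", exc)
    finish(
        "beta_diversity",
        t0,
        n_sites_functional=len(fun.sites),
        n_excluded=len(fun.excluded_sites),
    )

    # --- GDM ---------------------------------------------------------
    t0 = time.time()
    gdm_preds = [p for p in retained if p != "heterogeneity"]
    fits = {}
    pair_tables = {}
    try:
        for facet, dmat in (("taxonomic", tax), ("functional", fun)):
            pairs = build_site_pairs(dmat, env, gdm_preds)
            if len(pairs) > cfg.gdm_pair_cap:
                rng = np.random.default_rng(seeds[6])
                pairs = pairs.iloc[
                    rng.choice(len(pairs), cfg.gdm_pair_cap, replace=False)
                ].reset_index(drop=True)
                manifest["notes"].append(
                    f"{facet}: site pairs subsampled to {cfg.gdm_pair_cap}"
                )
            fit = fit_gdm(pairs, gdm_preds)
            fits[facet] = fit
            pair_tables[facet] = pairs
            imp = predictor_importance(fit)
            imp.to_csv(out / f"gdm_{facet}_importance.csv")
            summary = pd.DataFrame(
                {
                    "predictor": list(fit.coefficients),
                    "coef_1": [fit.coefficients[p][0] for p in fit.coefficients],
                    "coef_2": [fit.coefficients[p][1] for p in fit.coefficients],
                    "coef_3": [fit.coefficients[p][2] for p in fit.coefficients],
                }
            )
            summary.to_csv(out / f"gdm_{facet}_coefficients.csv", index=False)
            splines = []
            for p in fit.coefficients:
                grid = np.linspace(fit.knots[p][0], fit.knots[p][2], 100)
                splines.append(
                    pd.DataFrame(
                        {"predictor": p, "x": grid, "f": fit.transform(p, grid)}
                    )
                )
            pd.concat(splines).to_csv(out / f"gdm_{facet}_splines.csv", index=False)
    except Exception as exc:  # noqa: BLE001
        abort("gdm", exc)
    finish(
        "gdm",
        t0,
        deviance_explained={f: fits[f].deviance_explained for f in fits},
    )

    # --- deviance partition -----------------------------------------
    t0 = time.time()
    try:
        parts = {}
        for facet, pairs in pair_tables.items():
            part = partition_deviance(pairs, gdm_preds)
            part.as_frame().to_csv(out / f"gdm_{facet}_partition.csv")
            parts[facet] = part.as_frame()["deviance_explained"].to_dict()
    except Exception as exc:  # noqa: BLE001
        abort("partition", exc)
    finish("partition", t0, partitions=parts)

    # --- RGB ordination ---------------------------------------------
    t0 = time.time()
    try:
        for facet, fit in fits.items():
            dmat = tax if facet == "taxonomic" else fun
            pairs_all = build_site_pairs(dmat, env, gdm_preds)
            pred = predicted_matrix(fit, pairs_all, dmat.sites)
            rgb = rgb_ordination(pred)
            rgb.rename_axis("site").to_csv(out / f"rgb_{facet}.csv")
    except Exception as exc:  # noqa: BLE001
        abort("rgb_ordination", exc)
    finish("rgb_ordination", t0)

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
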