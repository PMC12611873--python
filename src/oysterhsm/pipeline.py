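"""End-to-end pipeline: simulate/load -> screen -> fit -> influence ->
project -> estimate, with one seed governing every random draw."""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import abundance as abn
from . import covariates as cov
from . import field_summary as fs
from . import influence as infl
from . import io as hio
from . import occurrence as occ
from . import projection as proj
from .synth import GeneratorConfig, generate_projection_set, generate_survey, \
    sample_shell_lengths

log = logging.getLogger(__name__)

PREDICTORS = ["substrate_cover", "exposure", "min_salinity"]


@dataclass
class PipelineConfig:
    """Everything a run needs; one seed feeds every stage."""

    seed: int = 0
    generator: GeneratorConfig | None = None
    covariates: cov.CovariateConfig = field(default_factory=cov.CovariateConfig)
    n_splits: int = 100
    auc_min: float = 0.70
    tss_min: float = 0.50
    cv_folds: int = 6
    cv_repeats: int = 10
    n_trees: int = 500
    importance_runs: int = 3
    n_boot: int = 1000
    n_marinas: int = 54
    n_natural: int = 108
    n_lengths: int = 500  # shell lengths sampled per habitat for biomass
    lw_anchors: tuple = proj.DEFAULT_LW_ANCHORS

    def __post_init__(self):
        if self.generator is None:
            self.generator = GeneratorConfig(seed=self.seed)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        gen = d.pop("generator", None)
        cfg = cls(**{k: v for k, v in d.items() if k != "generator"})
        if gen:
            cfg.generator = GeneratorConfig(seed=cfg.seed, **gen)
        return cfg


@dataclass
class PipelineResult:
    sites: pd.DataFrame
    quadrats: pd.DataFrame
    screen: cov.ScreenReport
    comparison: fs.HabitatComparison | None
    ensemble: occ.EnsembleModel
    abundance_model: abn.AbundanceModel
    occurrence_importance: pd.DataFrame
    abundance_importance: pd.DataFrame
    projection: pd.DataFrame | None
    projected: pd.DataFrame | None
    estimates: list[proj.HabitatEstimate]
    estimates_df: pd.DataFrame | None


def _seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31 - 1) for s in ss.generate_state(n)]


def run_pipeline(
    config: PipelineConfig,
    out_dir=None,
    sites: pd.DataFrame | None = None,
    quadrats: pd.DataFrame | None = None,
    projection_sites: pd.DataFrame | None = None,
    skip_projection: bool = False,
) -> PipelineResult:
    """Run the full workflow on synthetic (default) or supplied survey data.

    When ``projection_sites`` is omitted and ``skip_projection`` is true, the
    run stops after model fitting and influence analysis with a notice.
    Identical config and seed reproduce byte-identical output tables.
    """
    s_committee, s_abund, s_imp1, s_imp2, s_boot, s_len = _seeds(config.seed, 6)

    stage = "simulate"
    try:
        if sites is None or quadrats is None:
            sites, quadrats = generate_survey(config.generator)
            log.info("stage=simulate sites=%d quadrats=%d seed=%d",
                     len(sites), len(quadrats), config.generator.seed)
        if projection_sites is None and not skip_projection:
            projection_sites = generate_projection_set(
                config.generator, config.n_marinas, config.n_natural)

        stage = "covariates"
        screen = cov.collinearity_screen(sites[PREDICTORS], config.covariates)
        log.info("stage=covariates flagged_pairs=%d max_vif=%.2f",
                 len(screen.flagged_pairs), float(np.nanmax(screen.vif.to_numpy())))

        stage = "field_summary"
        site_table = fs.site_abundance_table(sites, quadrats,
                                             config.generator.quadrat_area)
        presence_sites = site_table[site_table["observed_presence"]]
        counts = presence_sites.groupby("habitat").size()
        if len(counts) >= 2 and (counts >= 2).all():
            comparison = fs.habitat_comparison(presence_sites)
            log.info("stage=field_summary F=%.2f p=%.3f", comparison.f_statistic,
                     comparison.p_value)
        else:
            comparison = None
            log.info("stage=field_summary comparison skipped "
                     "(a habitat has < 2 presence sites)")

        stage = "occurrence"
        fq = fs.first_quadrat_table(sites, quadrats)
        committee = occ.fit_committee(fq, PREDICTORS, n_splits=config.n_splits,
                                      seed=s_committee)
        ensemble = occ.build_ensemble(committee, fq, auc_min=config.auc_min,
                                      tss_min=config.tss_min)
        log.info("stage=occurrence included=%d/%d cutoff=%.3f calib_auc=%.3f",
                 len(ensemble.members), committee.n_attempted,
                 ensemble.cutoff, ensemble.calibration_auc)

        stage = "abundance"
        ab_data = presence_sites.copy()
        ab_data["substrate_cover"] = ab_data["mean_substrate"]
        model = abn.fit_abundance(ab_data, PREDICTORS, folds=config.cv_folds,
                                  repeats=config.cv_repeats,
                                  n_trees=config.n_trees, seed=s_abund)
        log.info("stage=abundance cv_rmse=%.3f smearing=%.3f bias=(%.2f, %.2f)",
                 model.cv_rmse, model.smearing, model.bias_intercept,
                 model.bias_slope)

        stage = "influence"
        occ_imp = infl.permutation_importance(
            infl.occurrence_predictor(ensemble), fq, PREDICTORS,
            n_runs=config.importance_runs, seed=s_imp1)
        ab_imp = infl.permutation_importance(
            infl.abundance_log_predictor(model), ab_data, PREDICTORS,
            n_runs=config.importance_runs, seed=s_imp2)
        log.info("stage=influence occ_top=%s abn_top=%s",
                 occ_imp.loc[occ_imp["importance"].idxmax(), "variable"],
                 ab_imp.loc[ab_imp["importance"].idxmax(), "variable"])

        projected, estimates, est_df = None, [], None
        if projection_sites is None:
            log.info("stage=projection skipped (no projection table)")
        else:
            stage = "projection"
            projected = proj.project(ensemble, model, projection_sites,
                                     config.covariates)
            lw = proj.lw_calibrate(config.lw_anchors)
            len_rng = np.random.default_rng(s_len)
            rocky = projected["substrate_cover"] > 0
            natural_mask = projected["habitat"].isin(["natural", "natural_rocky"])
            natural_area = float(projected.loc[natural_mask, "area_m2"].sum())
            rocky_area = natural_area * float(
                (rocky & natural_mask).sum() / max(natural_mask.sum(), 1))
            marina_area = float(
                projected.loc[projected["habitat"] == "marina", "area_m2"].sum())
            strata = [
                ("marina", projected["habitat"] == "marina", marina_area, "marina"),
                ("natural_rocky", natural_mask & rocky, rocky_area, "natural_rocky"),
                ("natural_overall", natural_mask, natural_area, "natural_rocky"),
            ]
            for i, (name, mask, area, len_habitat) in enumerate(strata):
                if not mask.any():
                    continue
                lengths = sample_shell_lengths(config.generator, len_habitat,
                                               config.n_lengths, len_rng)
                freqs = proj.length_class_frequencies(lengths)
                estimates.append(proj.estimate_habitat(
                    projected[mask], name, area, freqs, lw,
                    n_boot=config.n_boot, seed=s_boot + i))
            est_df = proj.estimates_table(estimates)
            log.info("stage=estimate strata=%d", len(estimates))
    except Exception as e:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {e}") from e

    result = PipelineResult(
        sites=sites, quadrats=quadrats, screen=screen, comparison=comparison,
        ensemble=ensemble, abundance_model=model,
        occurrence_importance=occ_imp, abundance_importance=ab_imp,
        projection=projection_sites, projected=projected,
        estimates=estimates, estimates_df=est_df,
    )
    if out_dir is not None:
        _write_outputs(result, config, out_dir)
    return result


def _write_outputs(result: PipelineResult, config: PipelineConfig, out_dir):
    out_dir = Path(out_dir)
    tables = {
        "sites": result.sites,
        "quadrats": result.quadrats,
        "occurrence_importance": result.occurrence_importance,
        "abundance_importance": result.abundance_importance,
    }
    if result.projection is not None:
        tables["projection"] = result.projection
    if result.projected is not None:
        tables["projected"] = result.projected
    if result.estimates_df is not None:
        tables["estimates"] = result.estimates_df
    hio.write_tables(out_dir, **tables)
    (out_dir / "screen.json").write_text(result.screen.to_json() + "\n")
    hio.write_manifest(out_dir, config.__dict__ | {
        "generator": config.generator.__dict__}, config.seed)
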