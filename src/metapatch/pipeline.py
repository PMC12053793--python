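"""End-to-end analysis pipeline: surveys in, JSON report out.

Runs the full chain -- pairing, neighbourhood covariates, event summary,
distance-only colonisation/extinction models, covariate models (with an
optional spatial random effect and AICc comparison), covariate-vs-distance
trends, extinction-outcome classification, observed-occupancy models, the
Levins equilibrium curve with bootstrap envelope, and the containment
comparison -- with every stage optional and every stochastic stage seeded.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import inference, metapop, survey

logger = logging.getLogger(__name__)

ALL_STAGES = ("events", "trends", "covariate_models", "cause_trends",
              "occupancy", "equilibrium", "bootstrap", "comparison")


@dataclass
class PipelineConfig:
    """Knobs of one analysis run."""

    radius_m: float = 500.0
    bootstrap_B: int = 1000
    level: float = 0.95
    seed: int = 0
    grid_size: int = 200
    stages: tuple = ALL_STAGES
    spatial: bool = True          # fit covariate models with the spatial term too
    dense_cap: int = 4000
    outdir: str | None = None
    figures: bool = False

    def __post_init__(self):
        self.stages = tuple(self.stages)
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stage(s): {sorted(unknown)}")
        if self.bootstrap_B < 1:
            raise ValueError("bootstrap_B must be >= 1")
        if not 0.0 < self.level < 1.0:
            raise ValueError("level must lie in (0, 1)")


def _tests_to_list(tests):
    return [dataclasses.asdict(t) for t in tests]


def prepare_pairs(t1: pd.DataFrame, t2: pd.DataFrame, config: PipelineConfig) -> pd.DataFrame:
    """Pair the snapshots, compute local abundance and the derived model
    covariates (log10(x+1) transforms)."""
    pairs = survey.pair_surveys(t1, t2)
    pairs = survey.local_abundance(pairs, config.radius_m)
    pairs["log10_L"] = np.log10(pairs["L_t1"] + 1.0)
    pairs["log10_N"] = np.log10(pairs["N_t1"] + 1.0)
    return pairs


def _covariate_block(spec, data, config):
    """Fit a covariate model without and (optionally) with the spatial random
    effect, with type II tests and the AICc comparison."""
    out = {}
    plain = inference.fit_glm(spec, data)
    out["glm"] = inference.fit_to_dict(plain)
    out["type2_tests"] = _tests_to_list(inference.type2_tests(spec, data))
    if config.spatial and plain.n_ <= config.dense_cap:
        sspec = dataclasses.replace(spec, spatial=True)
        spatial = inference.fit_glm(sspec, data)
        out["spatial_glmm"] = inference.fit_to_dict(spatial)
        out["spatial_type2_tests"] = _tests_to_list(
            inference.type2_tests(sspec, data, fit=spatial))
        out["aicc_with_spatial"] = float(spatial.aicc_)
        out["aicc_without_spatial"] = float(plain.aicc_)
        out["spatial_preferred"] = bool(spatial.aicc_ < plain.aicc_)
    elif config.spatial:
        out["spatial_glmm"] = {"skipped": f"n={plain.n_} exceeds dense cap {config.dense_cap}"}
    return out


def run_analyze(t1: pd.DataFrame, t2: pd.DataFrame, config: PipelineConfig | None = None) -> dict:
    """Run the configured stages and return a JSON-ready report."""
    config = config or PipelineConfig()
    report: dict = {"schema": "metapatch-report/1", "config": dataclasses.asdict(config)}
    pairs = prepare_pairs(t1, t2, config)
    report["n_pairs"] = int(len(pairs))

    col_pool, ext_pool = metapop.event_pools(pairs)
    have_col = len(col_pool) > 0 and col_pool["colonised"].nunique() > 1
    have_ext = len(ext_pool) > 0 and ext_pool["extinct"].nunique() > 1

    if "events" in config.stages:
        summary = survey.summarize_events(pairs)
        report["events"] = dataclasses.asdict(summary)

    grid = metapop.distance_grid(pairs, config.grid_size)

    c_fit = e_fit = None
    needs_distance_models = {"equilibrium", "bootstrap", "comparison"} & set(config.stages)
    if needs_distance_models:
        if have_col and have_ext:
            cspec = inference.ModelSpec(response="colonised", terms=("dist_km",))
            espec = inference.ModelSpec(response="extinct", terms=("dist_km",))
            c_fit = inference.fit_glm(cspec, col_pool)
            e_fit = inference.fit_glm(espec, ext_pool)
            report["distance_models"] = {
                "colonisation": inference.fit_to_dict(c_fit),
                "extinction": inference.fit_to_dict(e_fit),
                "colonisation_type2_tests": _tests_to_list(
                    inference.type2_tests(cspec, col_pool)),
                "extinction_type2_tests": _tests_to_list(
                    inference.type2_tests(espec, ext_pool)),
            }
        else:
            report["distance_models"] = {
                "skipped": "empty or degenerate colonisation/extinction pool"}

    if "covariate_models" in config.stages:
        block = {}
        if have_col:
            col_data = col_pool.rename(columns={"area_t2": "area"})
            spec = inference.ModelSpec(response="colonised",
                                       terms=("area", "log10_L"),
                                       interactions=(("area", "log10_L"),))
            block["colonisation"] = _covariate_block(spec, col_data, config)
            posthoc = inference.ModelSpec(response="colonised",
                                          terms=("dist_km", "area", "log10_L"))
            ph = inference.fit_glm(posthoc, col_data)
            block["colonisation_posthoc_distance"] = inference.fit_to_dict(ph)
            block["colonisation_posthoc_tests"] = _tests_to_list(
                inference.type2_tests(posthoc, col_data))
        else:
            block["colonisation"] = {"skipped": "empty colonisation pool"}
        if have_ext:
            ext_data = ext_pool.rename(columns={"area_t1": "area"})
            spec = inference.ModelSpec(response="extinct",
                                       terms=("log10_N", "log10_L", "area"),
                                       interactions=(("log10_N", "log10_L"),))
            block["extinction"] = _covariate_block(spec, ext_data, config)
            posthoc = inference.ModelSpec(response="extinct",
                                          terms=("dist_km", "log10_N", "area"))
            ph = inference.fit_glm(posthoc, ext_data)
            block["extinction_posthoc_distance"] = inference.fit_to_dict(ph)
        else:
            block["extinction"] = {"skipped": "empty extinction pool"}
        report["covariate_models"] = block

    if "trends" in config.stages:
        trends = {}
        for var, log in (("area_t1", False), ("area_t2", False),
                         ("N_t1", True), ("L_t1", True)):
            fit = inference.fit_gaussian_trend(var, pairs, log10p1=log)
            trends[("log10_" + var) if log else var] = inference.fit_to_dict(fit)
        report["trends"] = trends

    if "cause_trends" in config.stages:
        outcomes = survey.classify_extinction_outcomes(pairs)
        block = {"summary": survey.extinction_outcome_summary(outcomes)}
        complete = outcomes.loc[~outcomes["cause_missing"]].copy()
        if len(complete) and complete["still_suitable"].nunique() > 1:
            complete["still_suitable_f"] = complete["still_suitable"].astype(float)
            spec = inference.ModelSpec(response="still_suitable_f", terms=("dist_km",))
            block["still_suitable_model"] = inference.fit_to_dict(
                inference.fit_glm(spec, complete))
        unsuit = complete.loc[~complete["still_suitable"]].copy()
        for cause in ("succession", "wind"):
            unsuit[cause] = unsuit["causes"].map(lambda s: float(cause in s))
            if len(unsuit) and unsuit[cause].nunique() > 1:
                spec = inference.ModelSpec(response=cause, terms=("dist_km",))
                block[f"{cause}_model"] = inference.fit_to_dict(
                    inference.fit_glm(spec, unsuit))
        report["cause_trends"] = block

    if "occupancy" in config.stages:
        occ = {}
        for s in ("t1", "t2"):
            if pairs[f"suitable_{s}"].any():
                occ[s] = inference.fit_to_dict(metapop.observed_occupancy_model(pairs, s))
            else:
                occ[s] = {"skipped": "no suitable plots"}
        report["occupancy_models"] = occ

    eq = None
    if "equilibrium" in config.stages and c_fit is not None:
        eq = metapop.equilibrium_curve(c_fit, e_fit, grid)
        report["equilibrium"] = {
            "dist_km": grid.tolist(),
            "c_hat": eq.c_hat.tolist(),
            "e_hat": eq.e_hat.tolist(),
            "n_star": eq.n_star.tolist(),
        }

    if "bootstrap" in config.stages and have_col and have_ext:
        eq = metapop.bootstrap_envelope(col_pool, ext_pool, grid,
                                        B=config.bootstrap_B, level=config.level,
                                        seed=config.seed)
        report["bootstrap"] = {
            "B": eq.B, "n_failed": eq.n_failed, "seed": config.seed,
            "envelope_lo": eq.envelope_lo.tolist(),
            "envelope_hi": eq.envelope_hi.tolist(),
        }

    comp = None
    if "comparison" in config.stages and eq is not None and pairs["suitable_t2"].any():
        obs_fit = metapop.observed_occupancy_model(pairs, "t2")
        comp = metapop.compare_curves(eq, obs_fit, config.level)
        report["comparison"] = {
            "containment_fraction": comp.containment_fraction,
            "endpoints": comp.endpoints,
            "level": config.level,
        }

    if config.outdir is not None:
        _write_outputs(report, pairs, eq, comp, config)
    return report


def _write_outputs(report: dict, pairs: pd.DataFrame, eq, comp,
                   config: PipelineConfig) -> None:
    import pathlib

    out = pathlib.Path(config.outdir)
    out.mkdir(parents=True, exist_ok=True)
    survey.write_pairs(pairs, out / "pairs.csv")
    if eq is not None:
        eq.to_frame().to_csv(out / "equilibrium_curve.csv", index=False)
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2)
    if config.figures and eq is not None:
        from . import plots

        plots.plot_rates(eq, out / "rates.png")
        if comp is not None:
            plots.plot_occupancy(comp, eq, out / "occupancy.png")
    logger.info("wrote report bundle to %s", out)
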