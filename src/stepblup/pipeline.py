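"""End-to-end orchestration: simulate/QC -> kinships -> REML -> BLUP ->
DRP -> validation scenarios -> shaped reports.

The pipeline mirrors routine genetic-evaluation practice: variance
components are estimated once from the full data per trait, full-data
pedigree BLUP provides EBVs that are deregressed into DRPs, and the
cross-validation and forward scenarios then compare GBLUP against
ssGBLUP at fixed components.  Every stage logs what it consumed and
wrote; input files are never mutated.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as sio
from .deregress import drp_pipeline
from .evaluate import (
    build_scenario_data,
    compare_methods,
    make_cv_folds,
    make_forward_design,
    run_cross_validation,
    run_forward,
)
from .genomic import build_G, fill_missing_as_heterozygote, qc_filter
from .mme import build_design
from .pedigree import build_A_inverse, extract_A22
from .reml import ai_reml_bivariate, ai_reml_from_design
from .simulate import SimulationConfig, simulate_dataset

logger = logging.getLogger("stepblup")

__all__ = ["PipelineConfig", "PipelineResult", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full run (defaults: small synthetic profile)."""

    output_dir: str = "stepblup_run"
    # input files; None means "simulate"
    pedigree_file: str | None = None
    phenotype_file: str | None = None
    genotype_file: str | None = None  # PLINK .raw
    traits: list[str] | None = None
    simulation: SimulationConfig = field(default_factory=SimulationConfig.demo)
    # QC thresholds
    ind_call_rate: float = 0.90
    snp_call_rate: float = 0.90
    maf: float = 0.01
    hwe_p: float = 1e-5
    blend_weight: float = 0.9
    # validation design
    cv_folds: int = 5
    cv_repeats: int = 20
    n_test_generations: int = 2
    genetic_correlations: bool = True
    seed: int = 1

    def resolved_traits(self, dataset) -> list[str]:
        return list(self.traits) if self.traits else list(dataset.traits)


@dataclass
class PipelineResult:
    output_dir: Path
    parameters: pd.DataFrame
    correlations: pd.DataFrame | None
    predictive_ability: pd.DataFrame
    ebv_correlations: pd.DataFrame
    drp_counts: dict

    def __repr__(self) -> str:  # noqa: D105 - compact run summary
        return (
            f"PipelineResult(dir={self.output_dir}, traits={len(self.parameters)}, "
            f"scenarios={len(self.predictive_ability)})"
        )


def _stage(name):
    logger.info("stage: %s", name)
    return time.time()


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run every stage and write Table-shaped reports to the output dir."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "pipeline.log"
    handler = logging.FileHandler(log_path)
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(config, out)
    except Exception as e:  # annotate which stage failed, keep partial artifacts
        logger.error("pipeline failed: %s", e)
        raise
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(config: PipelineConfig, out: Path) -> PipelineResult:
    t0 = _stage("load-or-simulate")
    if config.pedigree_file:
        pedigree = sio.read_pedigree_csv(config.pedigree_file)
        phenotypes = sio.read_phenotypes_csv(config.phenotype_file)
        genotypes = (
            sio.read_plink_raw(config.genotype_file) if config.genotype_file else None
        )
    else:
        sim = simulate_dataset(config.simulation, seed=config.simulation.seed)
        pedigree, phenotypes, genotypes = sim.pedigree, sim.phenotypes, sim.genotypes
        sio.write_pedigree_csv(pedigree, out / "pedigree.csv")
        sio.write_phenotypes_csv(phenotypes, out / "phenotypes.csv")
        if genotypes is not None:
            sio.write_plink_raw(genotypes, out / "genotypes.raw")
    traits = config.resolved_traits(phenotypes)
    logger.info(
        "data: %d pedigree, %d records, %d genotyped (%.1fs)",
        pedigree.n,
        phenotypes.n_records,
        genotypes.n_individuals if genotypes is not None else 0,
        time.time() - t0,
    )

    t0 = _stage("qc")
    genotypes, qc_report = qc_filter(
        genotypes,
        ind_call_rate=config.ind_call_rate,
        snp_call_rate=config.snp_call_rate,
        maf=config.maf,
        hwe_p=config.hwe_p,
    )
    genotypes = fill_missing_as_heterozygote(genotypes)
    sio.write_qc_report(qc_report, out / "qc_report.json")

    t0 = _stage("kinships")
    A_inv = build_A_inverse(pedigree)
    A22 = extract_A22(pedigree, genotypes.ids)
    G = build_G(genotypes)
    logger.info("kinships done (%.1fs)", time.time() - t0)

    t0 = _stage("reml")
    vcs = {}
    designs = {}
    for trait in traits:
        design = build_design(phenotypes, pedigree.ids, trait=trait)
        designs[trait] = design
        vcs[trait] = ai_reml_from_design(design, A_inv)
        logger.info(
            "%s: h2=%.4f r=%.4f (%d iter)",
            trait,
            vcs[trait].h2,
            vcs[trait].repeatability or float("nan"),
            vcs[trait].n_iterations,
        )
    params = pd.DataFrame(
        [
            {
                "trait": t,
                "sigma_a2": v.sigma_a2,
                "sigma_p2": v.sigma_p2,
                "sigma_e2": v.sigma_e2,
                "h2": round(v.h2, 4),
                "h2_se": None if v.h2_se is None else round(v.h2_se, 4),
                "repeatability": None
                if v.repeatability is None
                else round(v.repeatability, 4),
                "repeatability_se": None
                if v.repeatability_se is None
                else round(v.repeatability_se, 4),
            }
            for t, v in vcs.items()
        ]
    ).set_index("trait")
    params.to_csv(out / "genetic_parameters.tsv", sep="\t")
    logger.info("reml done (%.1fs)", time.time() - t0)

    corr_frame = None
    if config.genetic_correlations and len(traits) > 1:
        t0 = _stage("genetic-correlations")
        rows = []
        for i, t1 in enumerate(traits):
            for t2 in traits[i + 1 :]:
                d = designs[t1]
                Y = np.column_stack([d.y, designs[t2].y])
                est = ai_reml_bivariate(Y, d.X, d.Z, d.W, A_inv)
                rows.append(
                    {
                        "trait_1": t1,
                        "trait_2": t2,
                        "genetic_correlation": round(est.genetic_correlation, 4),
                        "se": None
                        if est.genetic_correlation_se is None
                        else round(est.genetic_correlation_se, 4),
                        "genetic_covariance": round(float(est.sigma_a[0, 1]), 4),
                    }
                )
        corr_frame = pd.DataFrame(rows)
        corr_frame.to_csv(out / "genetic_correlations.tsv", sep="\t", index=False)
        logger.info("correlations done (%.1fs)", time.time() - t0)

    t0 = _stage("drp")
    drps = {}
    blup_ebv = {}
    drp_counts = {}
    for trait in traits:
        drp, excl, sol = drp_pipeline(phenotypes, pedigree, vcs[trait], trait=trait)
        drps[trait] = drp
        blup_ebv[trait] = sol.ebv
        drp_counts[trait] = {"n_drp": len(drp), "n_excluded": len(excl)}
        drp.to_csv(out / f"drp_{trait}.tsv", sep="\t")
        excl.to_csv(out / f"drp_{trait}_exclusions.tsv", sep="\t", index=False)
    logger.info("drp done (%.1fs)", time.time() - t0)

    t0 = _stage("validation")
    cv = make_cv_folds(
        genotypes.ids, k=config.cv_folds, repeats=config.cv_repeats, seed=config.seed
    )
    forward = make_forward_design(
        pedigree,
        genotypes.ids,
        phenotypes.boars,
        n_test_generations=config.n_test_generations,
    )
    forward.summary.to_csv(out / "forward_design.tsv", sep="\t")
    all_results = []
    ebv_corrs = []
    for trait in traits:
        data = build_scenario_data(
            phenotypes,
            trait,
            pedigree,
            vcs[trait],
            G,
            A22=A22,
            A_inv=A_inv,
            blend_weight=config.blend_weight,
        )
        drp_series = drps[trait]["drp"]
        all_results += run_cross_validation(data, drp_series, cv)
        fw_res, fw_corr = run_forward(
            data, drp_series, forward, pedigree_solution_ebv=blup_ebv[trait]
        )
        all_results += fw_res
        if len(fw_corr):
            ebv_corrs.append(fw_corr)
    pa = pd.DataFrame([r.to_dict() for r in all_results])
    pa.to_csv(out / "predictive_ability.tsv", sep="\t", index=False)
    comparison = compare_methods(all_results)
    comparison.to_csv(out / "method_comparison.tsv", sep="\t", index=False)
    ebv_corr_frame = (
        pd.concat(ebv_corrs, ignore_index=True) if ebv_corrs else pd.DataFrame()
    )
    ebv_corr_frame.to_csv(out / "ebv_correlations.tsv", sep="\t", index=False)
    logger.info("validation done (%.1fs)", time.time() - t0)

    meta = {
        "seed": config.seed,
        "traits": traits,
        "cv": {"k": config.cv_folds, "repeats": config.cv_repeats,
               "se_convention": "sd(fold correlations)/sqrt(k*repeats)"},
        "blend_weight": config.blend_weight,
        "drp_counts": drp_counts,
    }
    (out / "run_metadata.json").write_text(json.dumps(meta, indent=2, default=str))
    return PipelineResult(
        output_dir=out,
        parameters=params,
        correlations=corr_frame,
        predictive_ability=pa,
        ebv_correlations=ebv_corr_frame,
        drp_counts=drp_counts,
    )


def config_from_yaml(path) -> PipelineConfig:
    """Build a PipelineConfig from a YAML mapping (simulation nested)."""
    raw = sio.load_config(path) or {}
    sim_raw = raw.pop("simulation", None)
    sim = SimulationConfig(**sim_raw) if sim_raw else SimulationConfig.demo()
    known = {f.name for f in dataclasses.fields(PipelineConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown pipeline config keys: {sorted(unknown)}")
    return PipelineConfig(simulation=sim, **raw)
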