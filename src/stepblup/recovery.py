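"""Parameter-recovery studies: simulate under known truths, re-estimate.

These helpers drive the package's main self-validation: phenotypes are
simulated under the repeatability model at a reduced population scale
(~1,000 phenotyped boars with repeated records in a 12-generation
pedigree), AI-REML re-estimates the variance components, and the means
over seeded replicates are compared with the simulation truths.

For speed the animal effect is collapsed onto the recorded boars: the
restricted likelihood depends on the relationship matrix only through
``Z A Z' = Z_b A_bb Z_b'`` with ``A_bb`` the dense pedigree relationship
submatrix of the recorded boars, so estimating against ``K = A_bb``
yields *identical* REML estimates to the full-pedigree animal model
while shrinking the equation system by the non-recorded ancestors.
(The equivalence is asserted by a unit test.)
"""

from __future__ import annotations

import numpy as np
import scipy.linalg as la

from .mme import build_design
from .pedigree import extract_A22
from .reml import (
    GeneticCovarianceEstimate,
    VarianceComponents,
    ai_reml,
    ai_reml_bivariate,
)
from .simulate import SimulationConfig, simulate_dataset

__all__ = [
    "recovery_config",
    "single_trait_replicate",
    "bivariate_replicate",
    "recover_single_trait",
    "recover_genetic_correlation",
]


def recovery_config(
    variance_components: dict[str, tuple[float, float, float]],
    seed: int,
    records_per_boar_mean: float = 20.0,
    genetic_correlation: float | None = None,
) -> SimulationConfig:
    """Reduced-scale study config: ~950 boars, 12 generations.

    ``variance_components`` maps trait name -> (sigma_a^2, sigma_p^2,
    sigma_e^2); for two traits, ``genetic_correlation`` sets their
    genetic correlation (permanent-environment and residual effects stay
    uncorrelated across traits).
    """
    traits = list(variance_components)
    R = None
    if len(traits) == 2:
        rg = 0.0 if genetic_correlation is None else float(genetic_correlation)
        R = np.array([[1.0, rg], [rg, 1.0]])
    elif len(traits) > 2:
        R = np.eye(len(traits))
    return SimulationConfig(
        seed=seed,
        n_generations=12,
        n_founders=240,
        n_sires_per_gen=15,
        n_dams_per_gen=110,
        offspring_per_mating=2,
        pheno_generations=list(range(3, 12)),
        records_per_boar_mean=records_per_boar_mean,
        n_year_seasons=16,
        traits=traits,
        variance_components_per_trait=dict(variance_components),
        trait_means={t: 0.0 for t in traits},
        genetic_correlation_matrix=R,
        genotyping_proportion_by_generation=[0.0] * 12,
    )


def _collapsed_problem(config: SimulationConfig):
    """Simulate and build the boar-collapsed REML inputs."""
    sim = simulate_dataset(config, with_genotypes=False)
    boars = sim.phenotypes.boars
    A_bb = extract_A22(sim.pedigree, boars).toarray()
    cf = la.cho_factor(A_bb, lower=True, check_finite=False)
    K_inv = la.cho_solve(cf, np.eye(len(boars)), check_finite=False)
    K_inv = 0.5 * (K_inv + K_inv.T)
    return sim, boars, K_inv


def single_trait_replicate(
    vc_truth: tuple[float, float, float],
    seed: int,
    records_per_boar_mean: float = 20.0,
    trait: str = "T1",
) -> VarianceComponents:
    """One simulate-and-reestimate replicate for a single trait."""
    config = recovery_config(
        {trait: vc_truth}, seed=seed, records_per_boar_mean=records_per_boar_mean
    )
    sim, boars, K_inv = _collapsed_problem(config)
    design = build_design(sim.phenotypes, boars, trait=trait)
    return ai_reml(design.y, design.X, design.Z, design.W, K_inv)


def bivariate_replicate(
    vc_truth_1: tuple[float, float, float],
    vc_truth_2: tuple[float, float, float],
    genetic_correlation: float,
    seed: int,
    records_per_boar_mean: float = 15.0,
) -> GeneticCovarianceEstimate:
    """One replicate of the two-trait genetic-correlation recovery."""
    config = recovery_config(
        {"T1": vc_truth_1, "T2": vc_truth_2},
        seed=seed,
        records_per_boar_mean=records_per_boar_mean,
        genetic_correlation=genetic_correlation,
    )
    sim, boars, K_inv = _collapsed_problem(config)
    design = build_design(sim.phenotypes, boars, trait="T1")
    Y = sim.phenotypes.records[["T1", "T2"]].to_numpy(float)
    return ai_reml_bivariate(Y, design.X, design.Z, design.W, K_inv)


def recover_single_trait(
    vc_truth: tuple[float, float, float],
    n_replicates: int = 10,
    seed: int = 1,
    records_per_boar_mean: float = 20.0,
) -> dict:
    """Mean h2 and repeatability estimates over seeded replicates."""
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31 - 1)
    h2s, reps, fits = [], [], []
    for s in seeds:
        vc = single_trait_replicate(
            vc_truth, seed=int(s), records_per_boar_mean=records_per_boar_mean
        )
        h2s.append(vc.h2)
        reps.append(vc.repeatability)
        fits.append(vc)
    sa, sp2, se = vc_truth
    tot = sa + sp2 + se
    return {
        "h2_mean": float(np.mean(h2s)),
        "h2_sd": float(np.std(h2s, ddof=1)) if n_replicates > 1 else 0.0,
        "repeatability_mean": float(np.mean(reps)),
        "repeatability_sd": float(np.std(reps, ddof=1)) if n_replicates > 1 else 0.0,
        "h2_truth": sa / tot,
        "repeatability_truth": (sa + sp2) / tot,
        "n_replicates": n_replicates,
        "replicates": fits,
    }


def recover_genetic_correlation(
    vc_truth_1: tuple[float, float, float],
    vc_truth_2: tuple[float, float, float],
    genetic_correlation: float,
    n_replicates: int = 3,
    seed: int = 1,
    records_per_boar_mean: float = 15.0,
) -> dict:
    """Mean bivariate genetic-correlation estimate over replicates."""
    seeds = np.random.SeedSequence(seed).generate_state(n_replicates) % (2**31 - 1)
    rgs, ses, fits = [], [], []
    for s in seeds:
        est = bivariate_replicate(
            vc_truth_1,
            vc_truth_2,
            genetic_correlation,
            seed=int(s),
            records_per_boar_mean=records_per_boar_mean,
        )
        rgs.append(est.genetic_correlation)
        ses.append(est.genetic_correlation_se)
        fits.append(est)
    return {
        "rg_mean": float(np.mean(rgs)),
        "rg_sd": float(np.std(rgs, ddof=1)) if n_replicates > 1 else 0.0,
        "rg_se_mean": float(np.mean([s for s in ses if s is not None]))
        if any(s is not None for s in ses)
        else None,
        "rg_truth": float(genetic_correlation),
        "n_replicates": n_replicates,
        "replicates": fits,
    }
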