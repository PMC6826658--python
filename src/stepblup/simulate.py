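"""Synthetic pedigree / genotype / repeated-phenotype generator.

Emulates the data structure of a large Duroc AI-station population:
a multi-generation pedigree with overlapping sire/dam use, SNP-array
genotypes on a subset of animals, and repeated ejaculate records on
boars for five sperm-morphology-abnormality percentages (CT, BT, PD,
DD, DMR).  Phenotypes follow the repeatability animal model

    y_ij = year-season + age_slope * Age_ij + interval_slope * Intv_ij
           + a_i + p_i + e_ij

with a drawn as a pedigree polygenic effect (parent average plus a
Mendelian-sampling deviation whose variance shrinks with parental
inbreeding), p once per boar, and e per record.  All simulated truths
are retained so downstream estimators can be validated exactly.

The default parameter profile reproduces the statistical structure of
the study population (variance components, genetic correlations, trait
means, ~22.6 records per boar); :meth:`SimulationConfig.study_scale`
gives the full population size (~5,300 animals, ~36k SNPs) and
:meth:`SimulationConfig.demo` a small profile for quick runs and tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genomic import MISSING, GenotypeMatrix
from .mme import TraitDataset
from .pedigree import Pedigree, inbreeding_coefficients, read_and_validate_pedigree

__all__ = [
    "DEFAULT_TRAITS",
    "SimulationConfig",
    "TruthTable",
    "SimulatedData",
    "simulate_pedigree",
    "simulate_genotypes",
    "simulate_breeding_values",
    "simulate_phenotypes",
    "simulate_dataset",
]

#: five sperm-morphology abnormality traits with their default
#: (sigma_a^2, sigma_p^2, sigma_e^2) in %^2 and mean in %
DEFAULT_TRAITS: dict[str, dict] = {
    "CT": {"vc": (0.0016, 0.0047, 0.0494), "mean": 0.15},
    "BT": {"vc": (0.5960, 0.6929, 3.0432), "mean": 2.41},
    "PD": {"vc": (2.5734, 3.2141, 4.7412), "mean": 4.94},
    "DD": {"vc": (7.2729, 4.2530, 13.1157), "mean": 7.25},
    "DMR": {"vc": (2.2786, 2.8257, 3.4195), "mean": 2.82},
}

#: default genetic correlations among the five traits (order as above)
DEFAULT_GENETIC_CORRELATIONS = np.array(
    [
        [1.000, 0.955, 0.329, 0.207, 0.403],
        [0.955, 1.000, 0.325, 0.305, 0.378],
        [0.329, 0.325, 1.000, 0.607, 0.052],
        [0.207, 0.305, 0.607, 1.000, 0.207],
        [0.403, 0.378, 0.052, 0.207, 1.000],
    ]
)


class ConfigurationError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimulationConfig:
    """All knobs of the generator.  Defaults mirror the study population."""

    n_generations: int = 12
    n_founders: int = 240
    n_sires_per_gen: int = 30
    n_dams_per_gen: int = 230
    offspring_per_mating: int = 2
    monogamous: bool = False  # True: each sire serves exactly one dam

    n_snps: int = 36_254
    founder_maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0014
    genotyping_proportion_by_generation: Sequence[float] | None = None

    traits: list[str] = field(default_factory=lambda: list(DEFAULT_TRAITS))
    variance_components_per_trait: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: {k: v["vc"] for k, v in DEFAULT_TRAITS.items()}
    )
    trait_means: dict[str, float] = field(
        default_factory=lambda: {k: v["mean"] for k, v in DEFAULT_TRAITS.items()}
    )
    genetic_correlation_matrix: np.ndarray | None = None

    pheno_generations: Sequence[int] | None = None  # default: generations 6..11
    records_per_boar_mean: float = 22.6
    n_year_seasons: int = 16
    year_season_effect_sd: dict[str, float] | float | None = None  # default: residual SD
    age_slope: dict[str, float] | float | None = None  # default 0.02 * residual SD / month
    interval_slope: dict[str, float] | float | None = None  # default 0.01 * residual SD / day
    start_age_months_range: tuple[float, float] = (10.0, 14.0)
    mean_interval_days: float = 5.0

    seed: int = 20190710

    def __post_init__(self) -> None:
        counts = {
            "n_generations": self.n_generations,
            "n_founders": self.n_founders,
            "n_sires_per_gen": self.n_sires_per_gen,
            "n_dams_per_gen": self.n_dams_per_gen,
            "offspring_per_mating": self.offspring_per_mating,
            "n_snps": self.n_snps,
        }
        for k, v in counts.items():
            if v < 1:
                raise ConfigurationError(f"{k} must be >= 1, got {v}")
        lo, hi = self.founder_maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ConfigurationError("founder_maf_range must lie in (0, 0.5]")
        if not (0.0 <= self.missing_rate <= 1.0):
            raise ConfigurationError("missing_rate must be a proportion")
        for t in self.traits:
            vc = self.variance_components_per_trait[t]
            if any(v < 0 for v in vc):
                raise ConfigurationError(f"negative variance component for {t}: {vc}")
        R = self.corr_matrix()
        if not np.allclose(R, R.T):
            raise ConfigurationError("genetic correlation matrix must be symmetric")
        if not np.allclose(np.diag(R), 1.0):
            raise ConfigurationError("genetic correlation matrix needs unit diagonal")
        if np.linalg.eigvalsh(R).min() < -1e-8:
            raise ConfigurationError("genetic correlation matrix is not PSD")
        if self.genotyping_proportion_by_generation is not None:
            props = np.asarray(self.genotyping_proportion_by_generation, float)
            if ((props < 0) | (props > 1)).any():
                raise ConfigurationError("genotyping proportions must lie in [0, 1]")
        if self.records_per_boar_mean <= 0:
            raise ConfigurationError("records_per_boar_mean must be positive")

    # -- derived -----------------------------------------------------------
    @property
    def n_traits(self) -> int:
        return len(self.traits)

    def corr_matrix(self) -> np.ndarray:
        if self.genetic_correlation_matrix is not None:
            R = np.asarray(self.genetic_correlation_matrix, float)
        elif self.traits == list(DEFAULT_TRAITS):
            R = DEFAULT_GENETIC_CORRELATIONS
        else:
            R = np.eye(self.n_traits)
        return R

    def genetic_covariance(self) -> np.ndarray:
        sd = np.sqrt([self.variance_components_per_trait[t][0] for t in self.traits])
        return self.corr_matrix() * np.outer(sd, sd)

    def _per_trait(self, value, default_fn) -> np.ndarray:
        if value is None:
            return np.array([default_fn(t) for t in self.traits])
        if isinstance(value, dict):
            return np.array([value[t] for t in self.traits], float)
        return np.full(self.n_traits, float(value))

    def resolved_year_season_sd(self) -> np.ndarray:
        return self._per_trait(
            self.year_season_effect_sd,
            lambda t: np.sqrt(self.variance_components_per_trait[t][2]),
        )

    def resolved_age_slope(self) -> np.ndarray:
        return self._per_trait(
            self.age_slope,
            lambda t: 0.02 * np.sqrt(self.variance_components_per_trait[t][2]),
        )

    def resolved_interval_slope(self) -> np.ndarray:
        return self._per_trait(
            self.interval_slope,
            lambda t: 0.01 * np.sqrt(self.variance_components_per_trait[t][2]),
        )

    def resolved_pheno_generations(self) -> list[int]:
        if self.pheno_generations is not None:
            return list(self.pheno_generations)
        start = max(0, self.n_generations - 6)
        return list(range(start, self.n_generations))

    def resolved_genotyping_proportions(self) -> np.ndarray:
        if self.genotyping_proportion_by_generation is not None:
            props = np.asarray(self.genotyping_proportion_by_generation, float)
            if len(props) != self.n_generations:
                raise ConfigurationError(
                    "genotyping proportions must have one entry per generation"
                )
            return props
        props = np.zeros(self.n_generations)
        g = self.n_generations
        for gen, frac in zip(range(g - 8, g), [0, 0, 0.3, 0.3, 0.5, 0.6, 0.4, 0.4]):
            if gen >= 0:
                props[gen] = frac
        return props

    # -- profiles ----------------------------------------------------------
    @classmethod
    def study_scale(cls, **overrides) -> "SimulationConfig":
        """Full population scale: ~5,300 animals, ~1,300 phenotyped boars,
        ~1,600 genotyped animals x ~36k SNPs."""
        return cls(**overrides)

    @classmethod
    def demo(cls, **overrides) -> "SimulationConfig":
        """Small profile for examples and fast end-to-end runs."""
        params = dict(
            n_generations=8,
            n_founders=40,
            n_sires_per_gen=8,
            n_dams_per_gen=30,
            offspring_per_mating=3,
            n_snps=800,
            records_per_boar_mean=8.0,
            n_year_seasons=8,
            pheno_generations=list(range(3, 8)),
            genotyping_proportion_by_generation=[0, 0, 0, 0.5, 0.6, 0.6, 0.6, 0.6],
        )
        params.update(overrides)
        return cls(**params)


@dataclass
class TruthTable:
    """Simulated truths: everything needed to reconstruct phenotypes."""

    traits: list[str]
    breeding_values: pd.DataFrame  # animals x traits
    permanent_env: pd.DataFrame | None = None  # phenotyped boars x traits
    year_season_effects: pd.DataFrame | None = None  # classes x traits
    trait_means: pd.Series | None = None
    age_slope: pd.Series | None = None
    interval_slope: pd.Series | None = None
    record_fixed: pd.DataFrame | None = None  # per record, per trait
    record_residual: pd.DataFrame | None = None  # per record, per trait


@dataclass
class SimulatedData:
    """Bundle returned by :func:`simulate_dataset`."""

    config: SimulationConfig
    pedigree: Pedigree
    truth: TruthTable
    phenotypes: TraitDataset
    genotypes: GenotypeMatrix | None = None  # genotyped subset, may hold missing

    @property
    def genotyped_ids(self) -> pd.Index:
        return self.genotypes.ids if self.genotypes is not None else pd.Index([])


def _rng(config_or_seed) -> np.random.Generator:
    if isinstance(config_or_seed, np.random.Generator):
        return config_or_seed
    return np.random.default_rng(config_or_seed)


def simulate_pedigree(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> Pedigree:
    """Random-mating multi-generation pedigree with recorded sexes.

    Founders (generation 0) have unknown parents and an even sex split;
    each later generation draws ``n_sires_per_gen`` sires and
    ``n_dams_per_gen`` dams from the previous generation, mates each dam
    to one sire (a random sire, or a dedicated one if ``monogamous``)
    and produces ``offspring_per_mating`` offspring per mating.
    """
    rng = _rng(rng if rng is not None else config.seed)
    rows: list[tuple] = []
    next_id = 1
    sex0 = np.array(["M", "F"])[np.arange(config.n_founders) % 2]
    prev: list[tuple[int, str]] = []
    for i in range(config.n_founders):
        rows.append((next_id, 0, 0, 0, sex0[i]))
        prev.append((next_id, sex0[i]))
        next_id += 1
    for gen in range(1, config.n_generations):
        males = [a for a, s in prev if s == "M"]
        females = [a for a, s in prev if s == "F"]
        if not males or not females:
            raise ConfigurationError(f"generation {gen - 1} has no sires or no dams")
        sires = list(rng.choice(males, size=min(config.n_sires_per_gen, len(males)),
                                replace=False))
        dams = list(rng.choice(females, size=min(config.n_dams_per_gen, len(females)),
                               replace=False))
        gen_rows: list[list] = []
        for k, dam in enumerate(dams):
            if config.monogamous:
                sire = sires[k % len(sires)]
            else:
                sire = sires[rng.integers(len(sires))]
            for _ in range(config.offspring_per_mating):
                gen_rows.append([next_id, sire, dam, gen, None])
                next_id += 1
        # balanced sex ratio within each generation (shuffled half/half)
        k = len(gen_rows)
        sexes = np.array(["M", "F"])[np.arange(k) % 2]
        sexes = sexes[rng.permutation(k)]
        cur = []
        for row, sex in zip(gen_rows, sexes):
            row[4] = sex
            rows.append(tuple(row))
            cur.append((row[0], sex))
        prev = cur
    frame = pd.DataFrame(rows, columns=["id", "sire", "dam", "generation", "sex"])
    return read_and_validate_pedigree(frame)


def simulate_genotypes(
    pedigree: Pedigree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    ids=None,
) -> GenotypeMatrix:
    """Gene-drop unlinked SNPs through the pedigree.

    Founder genotypes are Binomial(2, p) with per-locus allele
    frequencies uniform on ``founder_maf_range``; each offspring receives
    one allele per parent (heterozygous parents transmit either allele
    with probability 1/2).  Missing codes are injected uniformly at
    ``missing_rate``.  ``ids`` restricts the returned matrix (default:
    all animals).
    """
    rng = _rng(rng if rng is not None else config.seed + 1)
    n, msnp = pedigree.n, config.n_snps
    lo, hi = config.founder_maf_range
    p = rng.uniform(lo, hi, size=msnp)
    codes = np.empty((n, msnp), dtype=np.int8)
    s, d = pedigree.sire_idx, pedigree.dam_idx
    for i in range(n):
        if s[i] < 0 and d[i] < 0:
            codes[i] = rng.binomial(2, p).astype(np.int8)
        else:
            half_s = (
                rng.random(msnp) < codes[s[i]] / 2.0
                if s[i] >= 0
                else rng.binomial(1, p).astype(bool)
            )
            half_d = (
                rng.random(msnp) < codes[d[i]] / 2.0
                if d[i] >= 0
                else rng.binomial(1, p).astype(bool)
            )
            codes[i] = half_s.astype(np.int8) + half_d.astype(np.int8)
    snp_ids = pd.Index([f"snp{j + 1}" for j in range(msnp)])
    if ids is not None:
        pos = pedigree.positions(ids)
        codes = codes[pos]
        out_ids = pd.Index(ids)
    else:
        out_ids = pedigree.ids
    if config.missing_rate > 0:
        mask = rng.random(codes.shape) < config.missing_rate
        codes = codes.copy()
        codes[mask] = MISSING
    return GenotypeMatrix(codes, out_ids, snp_ids)


def simulate_breeding_values(
    pedigree: Pedigree,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TruthTable:
    """Polygenic true breeding values via Mendelian sampling.

    Founders are drawn i.i.d. N(0, Sigma_a); descendants get the parent
    average plus a deviation with covariance
    ``0.5 (1 - (F_s + F_d)/2) Sigma_a`` (unknown parents contribute a
    zero average and a correspondingly larger deviation variance).
    """
    rng = _rng(rng if rng is not None else config.seed + 2)
    Sa = config.genetic_covariance()
    w, _ = np.linalg.eigh(Sa)
    if w.min() < -1e-10:
        raise ConfigurationError("genetic covariance matrix is not PSD")
    L = np.linalg.cholesky(Sa + 1e-12 * np.eye(len(Sa)))
    n, t = pedigree.n, config.n_traits
    F = inbreeding_coefficients(pedigree).to_numpy()
    s, d = pedigree.sire_idx, pedigree.dam_idx
    a = np.zeros((n, t))
    z = rng.standard_normal((n, t))
    for i in range(n):
        si, di = s[i], d[i]
        if si < 0 and di < 0:
            a[i] = L @ z[i]
        else:
            pa = np.zeros(t)
            known = [p for p in (si, di) if p >= 0]
            for pidx in known:
                pa += 0.5 * a[pidx]
            # Mendelian-sampling variance shrinks with parental inbreeding;
            # an unknown parent contributes its full founder variance share.
            if len(known) == 2:
                msv = 0.5 * (1.0 - 0.5 * (F[si] + F[di]))
            elif len(known) == 1:
                msv = 0.75 - 0.25 * F[known[0]]
            else:
                msv = 1.0
            a[i] = pa + np.sqrt(msv) * (L @ z[i])
    bv = pd.DataFrame(a, index=pedigree.ids, columns=config.traits)
    return TruthTable(traits=list(config.traits), breeding_values=bv)


def simulate_phenotypes(
    pedigree: Pedigree,
    truth: TruthTable,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> TraitDataset:
    """Repeated ejaculate records for boars of the phenotyped generations.

    Record counts are zero-truncated Poisson around
    ``records_per_boar_mean``; each record gets a uniformly assigned
    year-season class, an accumulating boar age (months) and a
    collection interval (days).  The truth table is extended in place
    with permanent-environment effects, year-season effects and the
    per-record fixed parts and residuals.
    """
    rng = _rng(rng if rng is not None else config.seed + 3)
    traits = config.traits
    t = len(traits)
    frame = pedigree.frame
    gens = set(config.resolved_pheno_generations())
    if "sex" in frame.columns:
        is_boar = (frame["sex"] == "M").to_numpy()
    else:
        is_boar = np.ones(len(frame), dtype=bool)
    mask = is_boar & frame["generation"].isin(gens).to_numpy()
    boars = frame.loc[mask, "id"].to_numpy()
    if len(boars) == 0:
        raise ConfigurationError("no boars fall in the phenotyped generations")

    sp2 = np.array([config.variance_components_per_trait[x][1] for x in traits])
    se2 = np.array([config.variance_components_per_trait[x][2] for x in traits])
    means = np.array([config.trait_means.get(x, 0.0) for x in traits])
    ys_sd = config.resolved_year_season_sd()
    age_b = config.resolved_age_slope()
    int_b = config.resolved_interval_slope()

    ys_eff = rng.normal(0.0, 1.0, size=(config.n_year_seasons, t)) * ys_sd
    pe = rng.normal(0.0, 1.0, size=(len(boars), t)) * np.sqrt(sp2)

    mean_extra = max(config.records_per_boar_mean - 1.0, 0.0)
    counts = 1 + rng.poisson(mean_extra, size=len(boars))

    bv = truth.breeding_values
    rec_rows = []
    fixed_rows = []
    resid_rows = []
    a_lo, a_hi = config.start_age_months_range
    for bidx, boar in enumerate(boars):
        k = counts[bidx]
        ys = rng.integers(0, config.n_year_seasons, size=k)
        start_age = rng.uniform(a_lo, a_hi)
        intervals = rng.gamma(4.0, config.mean_interval_days / 4.0, size=k)
        intervals[0] = 0.0
        ages = start_age + np.cumsum(intervals) / 30.44
        e = rng.normal(0.0, 1.0, size=(k, t)) * np.sqrt(se2)
        a_i = bv.loc[boar].to_numpy()
        for j in range(k):
            fixed = means + ys_eff[ys[j]] + age_b * ages[j] + int_b * intervals[j]
            yvals = fixed + a_i + pe[bidx] + e[j]
            rec_rows.append((boar, j + 1, f"ys{ys[j]}", ages[j], intervals[j], *yvals))
            fixed_rows.append(fixed)
            resid_rows.append(e[j])
    rec = pd.DataFrame(
        rec_rows,
        columns=["id", "record", "year_season", "age_months", "interval_days", *traits],
    )
    truth.permanent_env = pd.DataFrame(pe, index=pd.Index(boars, name="id"), columns=traits)
    truth.year_season_effects = pd.DataFrame(
        ys_eff, index=[f"ys{i}" for i in range(config.n_year_seasons)], columns=traits
    )
    truth.trait_means = pd.Series(means, index=traits)
    truth.age_slope = pd.Series(age_b, index=traits)
    truth.interval_slope = pd.Series(int_b, index=traits)
    truth.record_fixed = pd.DataFrame(fixed_rows, columns=traits, index=rec.index)
    truth.record_residual = pd.DataFrame(resid_rows, columns=traits, index=rec.index)
    return TraitDataset(records=rec, traits=list(traits))


def select_genotyped(
    pedigree: Pedigree, config: SimulationConfig, rng: np.random.Generator | None = None
) -> pd.Index:
    """Sample genotyped animals per generation at the configured rates."""
    rng = _rng(rng if rng is not None else config.seed + 4)
    props = config.resolved_genotyping_proportions()
    frame = pedigree.frame
    chosen = []
    for gen, prop in enumerate(props):
        if prop <= 0:
            continue
        ids = frame.loc[frame["generation"] == gen, "id"].to_numpy()
        k = int(round(prop * len(ids)))
        if k:
            chosen.extend(rng.choice(ids, size=k, replace=False))
    return pd.Index(sorted(chosen))


def simulate_dataset(
    config: SimulationConfig | None = None,
    with_genotypes: bool = True,
    seed: int | None = None,
) -> SimulatedData:
    """End-to-end simulation: pedigree, truths, phenotypes, genotypes."""
    config = config or SimulationConfig.demo()
    if seed is not None:
        config = replace(config, seed=seed)
    ped = simulate_pedigree(config)
    truth = simulate_breeding_values(ped, config)
    phen = simulate_phenotypes(ped, truth, config)
    geno = None
    if with_genotypes:
        gids = select_genotyped(ped, config)
        geno = simulate_genotypes(ped, config, ids=gids)
    return SimulatedData(
        config=config, pedigree=ped, truth=truth, phenotypes=phen, genotypes=geno
    )
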