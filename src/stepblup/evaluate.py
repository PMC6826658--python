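"""Validation designs: random cross-validation and forward prediction.

Two scenarios assess genomic predictive ability:

* 5-fold cross-validation over the genotyped animals, repeated 20
  times.  For GBLUP the training set is the remaining four folds of
  genotyped animals; for ssGBLUP every animal in the pedigree except
  the test fold trains the model.
* forward prediction: the youngest two generations are the test set,
  everything older trains — mimicking routine breeding use.

In both, raw repeated records (never DRPs) are the response; test-set
records are masked out of the training data; variance components stay
fixed at their full-data REML estimates; and predictive ability is the
plain Pearson correlation between predicted genetic values and the
full-data DRPs of the test animals.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genomic import blend_G
from .mme import ModelSpec, TraitDataset, build_design, solve_mme
from .pedigree import Pedigree, RelationshipMatrix
from .reml import VarianceComponents

__all__ = [
    "CVDesign",
    "ForwardDesign",
    "PredictiveAbilityResult",
    "make_cv_folds",
    "make_forward_design",
    "run_scenario",
    "predictive_ability",
    "compare_methods",
]


@dataclass
class CVDesign:
    """Reproducible k-fold partitions of the genotyped ids, per repeat."""

    k: int
    n_repeats: int
    base_seed: int
    folds: list[list[pd.Index]]  # folds[repeat][fold] -> ids

    def iter_tests(self):
        for r, rep in enumerate(self.folds):
            for f, ids in enumerate(rep):
                yield r, f, ids


@dataclass
class ForwardDesign:
    """Old-generations-train / young-generations-test split."""

    training_generations: list[int]
    test_generations: list[int]
    training_ids: pd.Index
    test_ids: pd.Index
    summary: pd.DataFrame  # Table-2-shaped counts


@dataclass
class PredictiveAbilityResult:
    """Per trait x method x scenario predictive-ability summary."""

    trait: str
    method: str
    scenario: str
    correlation: float
    se: float | None = None
    n_test: int | None = None
    fold_correlations: list = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "method": self.method,
            "scenario": self.scenario,
            "correlation": self.correlation,
            "se": self.se,
            "n_test": self.n_test,
        }


def make_cv_folds(
    genotyped_ids, k: int = 5, repeats: int = 20, seed: int = 0
) -> CVDesign:
    """Random fold assignments; repeat r uses seed + r; sizes differ by <= 1."""
    ids = pd.Index(genotyped_ids)
    if len(ids) < k:
        raise ValueError(f"need at least k={k} genotyped ids, have {len(ids)}")
    all_folds = []
    for r in range(repeats):
        rng = np.random.default_rng(seed + r)
        perm = rng.permutation(len(ids))
        splits = np.array_split(perm, k)
        all_folds.append([ids[np.sort(s)] for s in splits])
    return CVDesign(k=k, n_repeats=repeats, base_seed=seed, folds=all_folds)


def make_forward_design(
    pedigree: Pedigree,
    genotyped_ids,
    phenotyped_ids,
    n_test_generations: int = 2,
) -> ForwardDesign:
    """Split by generation: youngest ``n_test_generations`` are the test set."""
    gens = pedigree.generations
    max_gen = int(gens.max())
    test_gens = list(range(max_gen - n_test_generations + 1, max_gen + 1))
    train_gens = [g for g in sorted(set(gens)) if g not in test_gens]
    ids = pedigree.ids
    test_ids = ids[np.isin(gens, test_gens)]
    train_ids = ids[~np.isin(gens, test_gens)]
    gset = pd.Index(genotyped_ids)
    pset = pd.Index(phenotyped_ids)
    rows = []
    for name, part in (("training", train_ids), ("test", test_ids)):
        part = pd.Index(part)
        geno = part.intersection(gset)
        phen = part.intersection(pset)
        rows.append(
            {
                "dataset": name,
                "n_pedigree": len(part),
                "n_genotyped": len(geno),
                "n_phenotyped": len(phen),
                "n_pheno_and_geno": len(geno.intersection(phen)),
            }
        )
    return ForwardDesign(
        training_generations=train_gens,
        test_generations=test_gens,
        training_ids=pd.Index(train_ids),
        test_ids=pd.Index(test_ids),
        summary=pd.DataFrame(rows).set_index("dataset"),
    )


@dataclass
class ScenarioData:
    """Everything a prediction scenario needs, fixed across folds."""

    dataset: TraitDataset
    trait: str
    pedigree: Pedigree
    vc: VarianceComponents
    G: RelationshipMatrix  # over genotyped animals (role G or G_blended)
    H_inv: RelationshipMatrix | None = None  # over the full pedigree
    model: ModelSpec | None = None


def run_scenario(
    method: str,
    test_ids,
    data: ScenarioData,
) -> pd.Series:
    """Fit one scenario with the test set's phenotypes masked.

    ``method='GBLUP'`` fits only genotyped animals with K = G (records of
    genotyped training animals); ``'ssGBLUP'`` fits all non-test animals
    against K^-1 = H^-1.  Returns predicted genetic values for the test
    ids, which flow through the relationship matrix alone.
    """
    test_ids = pd.Index(test_ids)
    rec = data.dataset.records
    mask_keep = ~rec["id"].isin(test_ids).to_numpy()

    if method == "GBLUP":
        missing = test_ids.difference(data.G.ids)
        if len(missing):
            raise KeyError(f"test ids absent from G: {list(missing[:10])}")
        geno_ids = data.G.ids
        keep = mask_keep & rec["id"].isin(geno_ids).to_numpy()
        train = data.dataset.subset_records(keep)
        design = build_design(train, geno_ids, data.model, trait=data.trait)
        Gm = data.G.toarray()
        from .genomic import _sym_inverse

        K_inv = _sym_inverse(Gm, "G")
    elif method == "ssGBLUP":
        if data.H_inv is None:
            raise ValueError("ssGBLUP scenario needs H_inv in the data bundle")
        missing = test_ids.difference(data.H_inv.ids)
        if len(missing):
            raise KeyError(f"test ids absent from H: {list(missing[:10])}")
        train = data.dataset.subset_records(mask_keep)
        design = build_design(train, data.H_inv.ids, data.model, trait=data.trait)
        K_inv = data.H_inv
    else:
        raise ValueError(f"unknown method {method!r}")

    sol = solve_mme(
        design,
        K_inv,
        sigma_a2=data.vc.sigma_a2,
        sigma_e2=data.vc.sigma_e2,
        sigma_p2=data.vc.sigma_p2,
    )
    return sol.predict(test_ids)


def predictive_ability(
    predictions: pd.Series, drp: pd.Series, test_ids=None
) -> tuple[float, int]:
    """Plain Pearson correlation between predictions and DRPs.

    Ids lacking either value are excluded; fewer than 3 usable pairs or
    zero variance yields NaN.  Returns (correlation, n used).
    """
    ids = pd.Index(test_ids) if test_ids is not None else predictions.index
    common = ids.intersection(predictions.index).intersection(drp.index)
    x = predictions.loc[common].to_numpy(float)
    y = drp.loc[common].to_numpy(float)
    if len(common) < 3 or x.std() == 0 or y.std() == 0:
        return float("nan"), len(common)
    return float(np.corrcoef(x, y)[0, 1]), len(common)


def run_cross_validation(
    data: ScenarioData,
    drp: pd.Series,
    cv: CVDesign,
    methods: tuple[str, ...] = ("GBLUP", "ssGBLUP"),
) -> list[PredictiveAbilityResult]:
    """All folds x repeats x methods; SE = SD of fold correlations / sqrt(k*repeats)."""
    per_method: dict[str, list[float]] = {m: [] for m in methods}
    for _, _, test_ids in cv.iter_tests():
        for m in methods:
            preds = run_scenario(m, test_ids, data)
            r, _ = predictive_ability(preds, drp, test_ids)
            per_method[m].append(r)
    out = []
    for m in methods:
        vals = np.array(per_method[m], float)
        good = vals[~np.isnan(vals)]
        out.append(
            PredictiveAbilityResult(
                trait=data.trait,
                method=m,
                scenario="cross_validation",
                correlation=float(good.mean()) if len(good) else float("nan"),
                se=float(good.std(ddof=1) / np.sqrt(len(good))) if len(good) > 1 else None,
                n_test=len(good),
                fold_correlations=vals.tolist(),
            )
        )
    return out


def run_forward(
    data: ScenarioData,
    drp: pd.Series,
    design: ForwardDesign,
    methods: tuple[str, ...] = ("GBLUP", "ssGBLUP"),
    pedigree_solution_ebv: pd.Series | None = None,
) -> tuple[list[PredictiveAbilityResult], pd.DataFrame]:
    """Forward prediction; also returns the EBV cross-correlation table.

    The test set for predictive ability is the genotyped test-generation
    animals with a valid DRP.  When ``pedigree_solution_ebv`` (full-data
    pedigree BLUP EBVs) is supplied, the returned frame also reports the
    pairwise correlations between test-set EBV, GEBV and ssGEBV.
    """
    test_geno = design.test_ids.intersection(data.G.ids)
    results = []
    preds: dict[str, pd.Series] = {}
    for m in methods:
        pred = run_scenario(m, test_geno, data)
        preds[m] = pred
        r, n = predictive_ability(pred, drp, test_geno)
        results.append(
            PredictiveAbilityResult(
                trait=data.trait,
                method=m,
                scenario="forward",
                correlation=r,
                n_test=n,
            )
        )
    corr_rows = []
    if pedigree_solution_ebv is not None and {"GBLUP", "ssGBLUP"} <= set(preds):
        common = test_geno.intersection(pedigree_solution_ebv.index)
        trio = pd.DataFrame(
            {
                "EBV": pedigree_solution_ebv.loc[common],
                "GEBV": preds["GBLUP"].loc[common],
                "ssGEBV": preds["ssGBLUP"].loc[common],
            }
        )
        cm = trio.corr()
        corr_rows.append(
            {
                "trait": data.trait,
                "EBV_vs_GEBV": cm.loc["EBV", "GEBV"],
                "EBV_vs_ssGEBV": cm.loc["EBV", "ssGEBV"],
                "GEBV_vs_ssGEBV": cm.loc["GEBV", "ssGEBV"],
                "n": len(common),
            }
        )
    return results, pd.DataFrame(corr_rows)


def compare_methods(results: list[PredictiveAbilityResult]) -> pd.DataFrame:
    """Percentage improvement of ssGBLUP over GBLUP per trait and scenario.

    improvement% = 100 (r_ss - r_G) / r_G; a zero GBLUP base is flagged
    with NaN rather than raising.
    """
    frame = pd.DataFrame([r.to_dict() for r in results])
    rows = []
    for (trait, scen), grp in frame.groupby(["trait", "scenario"]):
        by = grp.set_index("method")["correlation"]
        if {"GBLUP", "ssGBLUP"} <= set(by.index):
            r_g, r_ss = float(by["GBLUP"]), float(by["ssGBLUP"])
            imp = 100.0 * (r_ss - r_g) / r_g if r_g != 0 else float("nan")
            rows.append(
                {
                    "trait": trait,
                    "scenario": scen,
                    "GBLUP": r_g,
                    "ssGBLUP": r_ss,
                    "improvement_pct": imp,
                }
            )
    return pd.DataFrame(rows)


def build_scenario_data(
    dataset: TraitDataset,
    trait: str,
    pedigree: Pedigree,
    vc: VarianceComponents,
    G: RelationshipMatrix,
    A22: RelationshipMatrix | None = None,
    A_inv: RelationshipMatrix | None = None,
    blend_weight: float = 0.9,
    model: ModelSpec | None = None,
) -> ScenarioData:
    """Assemble the fixed per-trait bundle (H^-1 built when possible)."""
    from .genomic import build_H_inverse
    from .pedigree import build_A_inverse, extract_A22

    H_inv = None
    if A22 is None:
        A22 = extract_A22(pedigree, G.ids)
    if A_inv is None:
        A_inv = build_A_inverse(pedigree)
    Gw = blend_G(G, A22, blend_weight)
    H_inv = build_H_inverse(A_inv, A22, Gw, G.ids)
    return ScenarioData(
        dataset=dataset,
        trait=trait,
        pedigree=pedigree,
        vc=vc,
        G=G,
        H_inv=H_inv,
        model=model,
    )
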