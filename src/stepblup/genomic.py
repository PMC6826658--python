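"""Genotype QC, VanRaden genomic relationships, blending, and H^-1.

The QC pipeline mirrors the PLINK-style filter chain used for 50k SNP
array data: individual call rate, SNP call rate, minor allele frequency,
and an exact Hardy-Weinberg test, applied in that fixed order, each on
the already-filtered matrix.  Remaining missing genotypes are replaced
by heterozygotes (code 1) — appropriate when the missing proportion is
tiny — and the VanRaden genomic relationship matrix

    G = Z Z' / sum_i 2 p_i (1 - p_i),   Z = M - 2p

is built from the filled matrix.  For single-step evaluations G is
blended with the pedigree submatrix, Gw = w G + (1-w) A22 (default
w = 0.9), and the inverse of the joint pedigree-genomic relationship
matrix is assembled as

    H^-1 = A^-1 + [0 0; 0 Gw^-1 - A22^-1]

with the correction confined to the genotyped block.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp

from .pedigree import RelationshipMatrix

__all__ = [
    "GenotypeMatrix",
    "QCReport",
    "HBlendConfig",
    "MISSING",
    "hwe_exact_test",
    "qc_filter",
    "fill_missing_as_heterozygote",
    "allele_frequencies",
    "build_G",
    "blend_G",
    "build_H_inverse",
]

#: integer code for a missing genotype
MISSING: int = -1


@dataclass
class GenotypeMatrix:
    """Individuals x SNPs additive genotype codes {0,1,2} with -1 = missing."""

    codes: np.ndarray
    ids: pd.Index
    snp_ids: pd.Index

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        self.ids = pd.Index(self.ids)
        self.snp_ids = pd.Index(self.snp_ids)
        if self.codes.shape != (len(self.ids), len(self.snp_ids)):
            raise ValueError("codes shape does not match id / SNP indexes")
        bad = ~np.isin(self.codes, [0, 1, 2, MISSING])
        if bad.any():
            raise ValueError(f"{bad.sum()} genotype codes outside {{0,1,2,missing}}")

    @property
    def n_individuals(self) -> int:
        return len(self.ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def missing_mask(self) -> np.ndarray:
        return self.codes == MISSING

    def subset(self, ind_mask=None, snp_mask=None) -> "GenotypeMatrix":
        codes, ids, snps = self.codes, self.ids, self.snp_ids
        if ind_mask is not None:
            codes, ids = codes[ind_mask], ids[ind_mask]
        if snp_mask is not None:
            codes, snps = codes[:, snp_mask], snps[snp_mask]
        return GenotypeMatrix(codes.copy(), ids, snps)


@dataclass
class QCReport:
    """Per-filter removal accounting for a QC run."""

    thresholds: dict
    steps: list = field(default_factory=list)  # (filter, axis, n_removed)
    n_individuals_in: int = 0
    n_snps_in: int = 0
    n_individuals_out: int = 0
    n_snps_out: int = 0

    def removed(self, axis: str) -> int:
        return sum(n for _, a, n in self.steps if a == axis)

    def to_dict(self) -> dict:
        return {
            "thresholds": self.thresholds,
            "steps": [
                {"filter": f, "axis": a, "removed": int(n)} for f, a, n in self.steps
            ],
            "individuals": {"in": self.n_individuals_in, "out": self.n_individuals_out},
            "snps": {"in": self.n_snps_in, "out": self.n_snps_out},
        }


@dataclass
class HBlendConfig:
    """Blend weight w on G (and 1-w on A22); the paper-style omega weight."""

    weight: float = 0.9

    def __post_init__(self) -> None:
        if not (0.0 < self.weight <= 1.0):
            raise ValueError(f"blend weight must be in (0, 1], got {self.weight}")


def hwe_exact_test(n_AA: int, n_Aa: int, n_aa: int, method: str = "exact") -> float:
    """Hardy-Weinberg equilibrium p-value from genotype counts.

    ``method='exact'`` is the SNP-HWE exact test: the p-value is the total
    probability of heterozygote-count configurations (given the allele
    counts) no more probable than the observed one.  ``method='chi2'``
    gives the 1-df chi-square approximation.  All-zero counts return 1.0
    with a warning (no information).
    """
    if min(n_AA, n_Aa, n_aa) < 0:
        raise ValueError("genotype counts must be non-negative")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        warnings.warn("HWE test on zero genotypes; returning p=1", stacklevel=2)
        return 1.0
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n_rare == 0 or n_rare == 2 * n:  # monomorphic: single configuration
        return 1.0

    if method == "chi2":
        p = (2 * n_AA + n_Aa) / (2 * n)
        exp = np.array([n * p * p, 2 * n * p * (1 - p), n * (1 - p) ** 2])
        obs = np.array([n_AA, n_Aa, n_aa], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            chi2 = np.nansum((obs - exp) ** 2 / np.where(exp > 0, exp, np.nan))
        from scipy.stats import chi2 as chi2_dist

        return float(chi2_dist.sf(chi2, df=1))
    if method != "exact":
        raise ValueError(f"unknown HWE method {method!r}")

    # Enumerate P(n_het | allele counts) over feasible heterozygote counts
    # via the standard ratio recurrence, in the same parity as n_rare.
    het_lo = n_rare % 2
    hets = np.arange(het_lo, min(n_rare, 2 * n - n_rare) + 1, 2)
    logp = np.zeros(len(hets))
    for k in range(1, len(hets)):
        h = hets[k]
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        # P(h) / P(h-2) = 4 * (rare_hom+1) * (common_hom+1) / (h * (h-1))
        logp[k] = logp[k - 1] + np.log(4.0 * (rare_hom + 1) * (common_hom + 1)) - np.log(
            h * (h - 1.0)
        )
    prob = np.exp(logp - logp.max())
    prob /= prob.sum()
    obs_h = n_Aa
    p_obs = prob[hets == obs_h][0]
    return float(min(1.0, prob[prob <= p_obs * (1 + 1e-12)].sum()))


def _genotype_counts(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    n2 = (codes == 2).sum(axis=0)
    n1 = (codes == 1).sum(axis=0)
    n0 = (codes == 0).sum(axis=0)
    return n2, n1, n0


def qc_filter(
    genotypes: GenotypeMatrix,
    ind_call_rate: float = 0.90,
    snp_call_rate: float = 0.90,
    maf: float = 0.01,
    hwe_p: float = 1e-5,
    hwe_method: str = "exact",
) -> tuple[GenotypeMatrix, QCReport]:
    """Apply the fixed QC chain: individual call -> SNP call -> MAF -> HWE.

    Each filter operates on the matrix as already reduced by the previous
    filters; the report records removals per step.  Raises if any step
    would remove every individual or every SNP.
    """
    report = QCReport(
        thresholds={
            "ind_call_rate": ind_call_rate,
            "snp_call_rate": snp_call_rate,
            "maf": maf,
            "hwe_p": hwe_p,
            "hwe_method": hwe_method,
        },
        n_individuals_in=genotypes.n_individuals,
        n_snps_in=genotypes.n_snps,
    )
    gm = genotypes

    called = ~gm.missing_mask
    ind_rate = called.mean(axis=1) if gm.n_snps else np.ones(gm.n_individuals)
    keep_ind = ind_rate >= ind_call_rate
    report.steps.append(("individual_call_rate", "individuals", int((~keep_ind).sum())))
    if not keep_ind.any():
        raise ValueError("QC removed all individuals (individual call rate)")
    gm = gm.subset(ind_mask=keep_ind)

    called = ~gm.missing_mask
    snp_rate = called.mean(axis=0)
    keep_snp = snp_rate >= snp_call_rate
    report.steps.append(("snp_call_rate", "snps", int((~keep_snp).sum())))
    gm = gm.subset(snp_mask=keep_snp)
    if gm.n_snps == 0:
        raise ValueError("QC removed all SNPs (SNP call rate)")

    p = allele_frequencies(gm, fill_first=False)
    folded = np.minimum(p, 1.0 - p)
    keep_snp = folded >= maf
    report.steps.append(("maf", "snps", int((~keep_snp).sum())))
    gm = gm.subset(snp_mask=keep_snp)
    if gm.n_snps == 0:
        raise ValueError("QC removed all SNPs (MAF)")

    n2, n1, n0 = _genotype_counts(gm.codes)
    pvals = np.array(
        [hwe_exact_test(a, b, c, method=hwe_method) for a, b, c in zip(n2, n1, n0)]
    )
    keep_snp = pvals >= hwe_p
    report.steps.append(("hwe", "snps", int((~keep_snp).sum())))
    gm = gm.subset(snp_mask=keep_snp)
    if gm.n_snps == 0:
        raise ValueError("QC removed all SNPs (HWE)")

    report.n_individuals_out = gm.n_individuals
    report.n_snps_out = gm.n_snps
    return gm, report


def fill_missing_as_heterozygote(genotypes: GenotypeMatrix) -> GenotypeMatrix:
    """Replace every missing code by the heterozygote code 1."""
    codes = genotypes.codes.copy()
    codes[codes == MISSING] = 1
    return GenotypeMatrix(codes, genotypes.ids, genotypes.snp_ids)


def allele_frequencies(genotypes: GenotypeMatrix, fill_first: bool = True) -> np.ndarray:
    """Observed frequency p of the counted allele per SNP.

    With ``fill_first`` (default) missing codes are treated as
    heterozygotes before counting, matching the single-matrix workflow;
    otherwise missing codes are excluded from the counts.
    """
    codes = genotypes.codes.astype(float)
    if fill_first:
        codes[genotypes.missing_mask] = 1.0
        return codes.mean(axis=0) / 2.0
    codes[genotypes.missing_mask] = np.nan
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        p = np.nanmean(codes, axis=0) / 2.0
    return np.where(np.isnan(p), 0.0, p)


def build_G(
    genotypes: GenotypeMatrix,
    freqs: np.ndarray | None = None,
    fold: bool = False,
) -> RelationshipMatrix:
    """VanRaden genomic relationship matrix.

    ``Z = M - 2p`` per SNP (codes 0,1,2 -> -2p, 1-2p, 2-2p) and
    ``G = Z Z' / sum_i 2 p_i (1 - p_i)``.  ``freqs`` supplies external
    allele frequencies; by default the observed counted-allele frequency
    is used (``fold=True`` folds to minor-allele frequencies instead, for
    sensitivity checks only — folding breaks the centering identity for
    SNPs with p > 0.5).
    """
    if genotypes.missing_mask.any():
        raise ValueError("missing genotypes remain; fill or QC first")
    p = np.asarray(freqs, dtype=float) if freqs is not None else allele_frequencies(genotypes)
    if fold:
        p = np.minimum(p, 1.0 - p)
    denom = float(np.sum(2.0 * p * (1.0 - p)))
    if denom <= 0:
        raise ValueError("zero VanRaden denominator (all SNPs monomorphic?)")
    Z = genotypes.codes.astype(float) - 2.0 * p
    G = (Z @ Z.T) / denom
    G = 0.5 * (G + G.T)
    return RelationshipMatrix(G, genotypes.ids, role="G")


def blend_G(
    G: RelationshipMatrix, A22: RelationshipMatrix, config: HBlendConfig | float = 0.9
) -> RelationshipMatrix:
    """Gw = w G + (1-w) A22, elementwise, in identical id order."""
    if isinstance(config, (int, float)):
        config = HBlendConfig(weight=float(config))
    if not G.ids.equals(A22.ids):
        raise ValueError("G and A22 id orders differ; reorder before blending")
    w = config.weight
    Gw = w * G.toarray() + (1.0 - w) * A22.toarray()
    return RelationshipMatrix(Gw, G.ids, role="G_blended")


def _sym_inverse(mat: np.ndarray, label: str) -> np.ndarray:
    """Symmetric positive-definite inverse with a logged jitter fallback."""
    mat = np.asarray(mat, dtype=float)
    try:
        c, low = la.cho_factor(mat, lower=True, check_finite=False)
    except la.LinAlgError:
        jitter = 1e-8 * np.trace(mat) / mat.shape[0]
        warnings.warn(
            f"{label} not positive definite; adding diagonal jitter {jitter:.2e} "
            "(consider blending with A22)",
            stacklevel=2,
        )
        try:
            c, low = la.cho_factor(
                mat + jitter * np.eye(mat.shape[0]), lower=True, check_finite=False
            )
        except la.LinAlgError as exc:
            raise np.linalg.LinAlgError(
                f"{label} singular even after jitter; blend with A22"
            ) from exc
    inv = la.cho_solve((c, low), np.eye(mat.shape[0]), check_finite=False)
    return 0.5 * (inv + inv.T)


def build_H_inverse(
    A_inv: RelationshipMatrix,
    A22: RelationshipMatrix,
    Gw: RelationshipMatrix,
    genotyped_ids=None,
) -> RelationshipMatrix:
    """H^-1 = A^-1 + (Gw^-1 - A22^-1) added into the genotyped block.

    ``A_inv`` spans the whole pedigree; ``A22``/``Gw`` span the genotyped
    animals (identical id order).  ``genotyped_ids`` defaults to
    ``Gw.ids``.  The correction is exactly zero outside the genotyped
    block.
    """
    gids = pd.Index(genotyped_ids) if genotyped_ids is not None else Gw.ids
    if not Gw.ids.equals(pd.Index(gids)) or not A22.ids.equals(pd.Index(gids)):
        raise ValueError("Gw/A22 id order must equal the genotyped id order")
    pos = A_inv.ids.get_indexer(gids)
    if (pos < 0).any():
        raise ValueError(f"genotyped ids missing from A^-1: {list(gids[pos < 0][:10])}")
    if len(gids) == 0:
        return RelationshipMatrix(A_inv.values.copy(), A_inv.ids, role="H_inverse")
    corr = _sym_inverse(Gw.toarray(), "Gw") - _sym_inverse(A22.toarray(), "A22")
    g = len(pos)
    corr_sp = sp.coo_matrix(
        (corr.ravel(), (np.repeat(pos, g), np.tile(pos, g))),
        shape=A_inv.values.shape,
    )
    Hinv = (sp.csc_matrix(A_inv.values) + corr_sp.tocsc()).tocsc()
    return RelationshipMatrix(Hinv, A_inv.ids, role="H_inverse")
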