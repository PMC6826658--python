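"""De-regressed proofs (DRPs) with parent-average removal.

Full-data pedigree-BLUP EBVs are shrunken toward the parent average
(PA), so correlating raw EBVs with genomic predictions double-counts
family information.  The Garrick-style deregression treats the EBV and
the PA as solutions of a two-equation mixed model, recovers the
information content of the individual's own (and progeny) data, and
returns the pseudo-observation ("DRP") that would regenerate the EBV
when re-shrunken — free of the PA contribution.  With

    lambda = (1 - h^2) / h^2
    alpha  = 1 / (0.5 - r2_PA)
    delta  = (0.5 - r2_PA) / (1 - r2_i)

    Z'Z_PA = lambda (0.5 alpha - 4) + 0.5 lambda sqrt(alpha^2 + 16/delta)
    Z'Z_i  = delta Z'Z_PA + 2 lambda (2 delta - 1)

the 2x2 system

    [ Z'Z_PA + 4 lambda   -2 lambda  ] [ PA    ]   [ y_PA ]
    [ -2 lambda           Z'Z_i + 2 lambda ] [ EBV_i ] = [ y_i ]

is inverted for the right-hand sides, and DRP = y_i / Z'Z_i with
reliability r2_DRP = 1 - lambda / (Z'Z_i + lambda).  Animals violating
the preconditions (r2_i <= r2_PA, r2_PA >= 0.5, unknown parents) are
skipped with a reason code rather than clamped.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .mme import MMESolution, TraitDataset, build_design, solve_mme
from .pedigree import Pedigree, build_A_inverse
from .reml import VarianceComponents

__all__ = [
    "DRPRecord",
    "parent_average",
    "garrick_deregress",
    "drp_pipeline",
]


@dataclass
class DRPRecord:
    """Deregressed proof for one animal (one trait)."""

    animal_id: object
    ebv: float
    reliability: float
    pa: float
    pa_reliability: float
    drp: float
    drp_reliability: float
    own_info: float  # Z'Z_i, the Garrick own-information weight
    weight: float | None = None  # optional analysis weight (stored, unused)


def parent_average(
    ebv: pd.Series, reliability: pd.Series, pedigree: Pedigree
) -> tuple[pd.DataFrame, list]:
    """PA = (EBV_sire + EBV_dam)/2 and r2_PA = (r2_sire + r2_dam)/4.

    Only animals with both parents known qualify; the second return
    value lists the excluded ids.
    """
    frame = pedigree.frame
    s, d = pedigree.sire_idx, pedigree.dam_idx
    ids = frame["id"].to_numpy()
    ok = (s >= 0) & (d >= 0)
    excluded = list(ids[~ok])
    sire_ids = ids[s[ok]]
    dam_ids = ids[d[ok]]
    pa = 0.5 * (ebv.loc[sire_ids].to_numpy() + ebv.loc[dam_ids].to_numpy())
    r2pa = 0.25 * (
        reliability.loc[sire_ids].to_numpy() + reliability.loc[dam_ids].to_numpy()
    )
    out = pd.DataFrame({"pa": pa, "r2_pa": r2pa}, index=pd.Index(ids[ok], name="id"))
    return out, excluded


def garrick_deregress(
    animal_id,
    ebv_i: float,
    r2_i: float,
    pa: float,
    r2_pa: float,
    h2: float,
    c_weight: float = 0.5,
) -> DRPRecord:
    """Deregress one EBV; raises ValueError with a reason code if skipped.

    ``c_weight`` is the assumed fraction of genetic variance not
    explained by markers, used only for the optional analysis weight
    w = (1 - h2) / ((c + (1 - r2_DRP)/r2_DRP) h2); the weight is stored
    but not used by the package's predictive-ability correlations.
    """
    if not (0.0 < h2 < 1.0):
        raise ValueError("h2-out-of-range")
    if r2_pa >= 0.5:
        raise ValueError("pa-reliability-too-high")
    if r2_i <= r2_pa:
        raise ValueError("no-own-information")
    if not (0.0 <= r2_pa and r2_i < 1.0):
        raise ValueError("reliability-out-of-range")
    lam = (1.0 - h2) / h2
    alpha = 1.0 / (0.5 - r2_pa)
    delta = (0.5 - r2_pa) / (1.0 - r2_i)
    ztz_pa = lam * (0.5 * alpha - 4.0) + 0.5 * lam * np.sqrt(alpha**2 + 16.0 / delta)
    ztz_i = delta * ztz_pa + 2.0 * lam * (2.0 * delta - 1.0)
    if ztz_i <= 0:
        raise ValueError("non-positive-own-information")
    y_pa = (ztz_pa + 4.0 * lam) * pa - 2.0 * lam * ebv_i
    y_i = -2.0 * lam * pa + (ztz_i + 2.0 * lam) * ebv_i
    drp = y_i / ztz_i
    r2_drp = 1.0 - lam / (ztz_i + lam)
    w = (1.0 - h2) / ((c_weight + (1.0 - r2_drp) / r2_drp) * h2)
    return DRPRecord(
        animal_id=animal_id,
        ebv=float(ebv_i),
        reliability=float(r2_i),
        pa=float(pa),
        pa_reliability=float(r2_pa),
        drp=float(drp),
        drp_reliability=float(r2_drp),
        own_info=float(ztz_i),
        weight=float(w),
    )


def deregress_table(
    ebv: pd.Series,
    reliability: pd.Series,
    pedigree: Pedigree,
    h2: float,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Deregress every eligible animal; returns (drp table, exclusion log)."""
    pa_table, no_parents = parent_average(ebv, reliability, pedigree)
    rows = []
    excl = [{"id": i, "reason": "unknown-parent"} for i in no_parents]
    for aid, row in pa_table.iterrows():
        try:
            rec = garrick_deregress(
                aid,
                float(ebv.loc[aid]),
                float(reliability.loc[aid]),
                float(row["pa"]),
                float(row["r2_pa"]),
                h2,
            )
        except ValueError as e:
            excl.append({"id": aid, "reason": str(e)})
            continue
        rows.append(
            {
                "id": aid,
                "ebv": rec.ebv,
                "reliability": rec.reliability,
                "pa": rec.pa,
                "r2_pa": rec.pa_reliability,
                "drp": rec.drp,
                "r2_drp": rec.drp_reliability,
                "own_info": rec.own_info,
                "weight": rec.weight,
            }
        )
    drp = pd.DataFrame(rows).set_index("id") if rows else pd.DataFrame(
        columns=["ebv", "reliability", "pa", "r2_pa", "drp", "r2_drp", "own_info",
                 "weight"]
    )
    return drp, pd.DataFrame(excl, columns=["id", "reason"])


def drp_pipeline(
    dataset: TraitDataset,
    pedigree: Pedigree,
    vc: VarianceComponents,
    trait: str | None = None,
    solution: MMESolution | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame, MMESolution]:
    """Pedigree BLUP on the full data, then deregression per animal.

    The full (never masked) dataset is the information source: DRPs are
    the fixed evaluation currency for all validation scenarios.  Returns
    (drp table, exclusion log, the BLUP solution used).
    """
    trait = trait or dataset.traits[0]
    if solution is None:
        design = build_design(dataset, pedigree.ids, trait=trait)
        A_inv = build_A_inverse(pedigree)
        solution = solve_mme(
            design,
            A_inv,
            sigma_a2=vc.sigma_a2,
            sigma_e2=vc.sigma_e2,
            sigma_p2=vc.sigma_p2,
            compute_pev=True,
        )
    drp, excl = deregress_table(
        solution.ebv, solution.reliability, pedigree, h2=vc.h2
    )
    return drp, excl, solution
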