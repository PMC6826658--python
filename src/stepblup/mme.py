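"""Repeatability-model mixed-model equations.

The single-trait repeatability animal model is

    y = X b + Z a + W p + e,
    a ~ N(0, K sigma_a^2),  p ~ N(0, I sigma_p^2),  e ~ N(0, I sigma_e^2)

where y holds repeated records (one row per ejaculate), b the fixed
effects (year-season classes plus the age and collection-interval
covariates), a the additive genetic values of *all* animals indexed by
the relationship matrix K (A, G or H), and p the permanent-environment
effect of each boar with records.  Henderson's MME are

    [X'X      X'Z              X'W        ] [b]   [X'y]
    [Z'X      Z'Z + K^-1 la    Z'W        ] [a] = [Z'y]
    [W'X      W'Z              W'W + I lp ] [p]   [W'y]

with la = sigma_e^2/sigma_a^2 and lp = sigma_e^2/sigma_p^2.  Animals
without records receive breeding values through K; prediction-error
variances come from the animal block of the inverse coefficient matrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp

from .pedigree import RelationshipMatrix

__all__ = [
    "TraitDataset",
    "ModelSpec",
    "Design",
    "MMESolution",
    "build_design",
    "solve_mme",
    "predict_genetic_values",
]


@dataclass
class TraitDataset:
    """Repeated ejaculate records for one or more traits.

    ``records`` has one row per record with columns ``id``,
    ``year_season``, ``age_months``, ``interval_days`` and one column per
    trait (percent units).
    """

    records: pd.DataFrame
    traits: list[str]

    def __post_init__(self) -> None:
        needed = {"id", "year_season", "age_months", "interval_days", *self.traits}
        missing = needed - set(self.records.columns)
        if missing:
            raise ValueError(f"records missing columns {sorted(missing)}")
        for t in self.traits:
            if not np.isfinite(self.records[t].to_numpy(float)).all():
                raise ValueError(f"non-finite values in trait {t!r}")
        if (self.records["age_months"].to_numpy(float) <= 0).any():
            raise ValueError("ages must be positive")
        if (self.records["interval_days"].to_numpy(float) < 0).any():
            raise ValueError("collection intervals must be non-negative")

    @property
    def n_records(self) -> int:
        return len(self.records)

    @property
    def boars(self) -> pd.Index:
        return pd.Index(pd.unique(self.records["id"]))

    def subset_records(self, mask: np.ndarray) -> "TraitDataset":
        return TraitDataset(self.records.loc[np.asarray(mask)].copy(), list(self.traits))


@dataclass
class ModelSpec:
    """Which terms enter the repeatability model."""

    fixed_classes: Sequence[str] = ("year_season",)
    covariates: Sequence[str] = ("age_months", "interval_days")
    permanent_env: bool | None = None  # None = auto (present iff repeated records)


@dataclass
class Design:
    """Design matrices of one trait's records against a given animal order."""

    X: np.ndarray
    Z: sp.csr_matrix
    W: sp.csr_matrix  # shape (n, 0) when the pe term is dropped
    y: np.ndarray
    x_names: list[str]
    animal_ids: pd.Index
    pe_ids: pd.Index
    covariate_means: dict[str, float] = field(default_factory=dict)
    record_index: np.ndarray | None = None  # provenance of rows in the source table

    @property
    def n(self) -> int:
        return len(self.y)

    @property
    def has_pe(self) -> bool:
        return self.W.shape[1] > 0


def build_design(
    dataset: TraitDataset,
    animal_ids: Sequence,
    spec: ModelSpec | None = None,
    trait: str | None = None,
) -> Design:
    """Incidence and covariate matrices for one trait.

    X holds an intercept, reference-dropped dummies for each fixed class,
    and mean-centered covariates (slopes are still on the original
    scale).  Z maps records to animal effects over *all* ``animal_ids``
    (the K order); W maps records to per-boar permanent-environment
    effects and is dropped (with a warning) if no boar repeats.
    """
    spec = spec or ModelSpec()
    trait = trait or dataset.traits[0]
    rec = dataset.records
    n = len(rec)
    y = rec[trait].to_numpy(float)

    cols = [np.ones(n)]
    names = ["intercept"]
    for cls in spec.fixed_classes:
        levels = pd.unique(rec[cls])
        counts = rec[cls].value_counts()
        levels = [lv for lv in levels if counts[lv] > 0]
        for lv in sorted(levels, key=str)[1:]:  # first level = reference
            cols.append((rec[cls] == lv).to_numpy(float))
            names.append(f"{cls}={lv}")
    means: dict[str, float] = {}
    for cov in spec.covariates:
        v = rec[cov].to_numpy(float)
        means[cov] = float(v.mean())
        cols.append(v - means[cov])
        names.append(cov)
    X = np.column_stack(cols)

    animal_ids = pd.Index(animal_ids)
    zpos = animal_ids.get_indexer(rec["id"])
    if (zpos < 0).any():
        bad = list(pd.unique(rec.loc[zpos < 0, "id"]))[:10]
        raise ValueError(f"record ids absent from the relationship index: {bad}")
    Z = sp.csr_matrix(
        (np.ones(n), (np.arange(n), zpos)), shape=(n, len(animal_ids))
    )

    counts = rec["id"].value_counts()
    use_pe = spec.permanent_env
    if use_pe is None:
        use_pe = bool((counts > 1).any())
    elif use_pe and not (counts > 1).any():
        warnings.warn("no boar has repeated records; dropping permanent-environment term")
        use_pe = False
    if use_pe:
        pe_ids = pd.Index(pd.unique(rec["id"]))
        wpos = pe_ids.get_indexer(rec["id"])
        W = sp.csr_matrix((np.ones(n), (np.arange(n), wpos)), shape=(n, len(pe_ids)))
    else:
        pe_ids = pd.Index([])
        W = sp.csr_matrix((n, 0))

    return Design(
        X=X,
        Z=Z,
        W=W,
        y=y,
        x_names=names,
        animal_ids=animal_ids,
        pe_ids=pe_ids,
        covariate_means=means,
        record_index=rec.index.to_numpy(),
    )


@dataclass
class MMESolution:
    """Solutions of the repeatability-model MME for one trait."""

    fixed: pd.Series
    ebv: pd.Series
    pe: pd.Series
    pev: pd.Series | None
    reliability: pd.Series | None
    sigma_a2: float
    sigma_p2: float | None
    sigma_e2: float

    def predict(self, ids: Sequence) -> pd.Series:
        return predict_genetic_values(self, ids)


def _as_kinv_matrix(K_inv) -> tuple[np.ndarray | sp.spmatrix, pd.Index | None]:
    if isinstance(K_inv, RelationshipMatrix):
        return K_inv.values, K_inv.ids
    return K_inv, None


def assemble_mme(
    design: Design, K_inv, sigma_a2: float, sigma_p2: float | None, sigma_e2: float
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Dense lambda-scaled coefficient matrix, right-hand side, and layout."""
    Kv, kids = _as_kinv_matrix(K_inv)
    if kids is not None and not kids.equals(design.animal_ids):
        raise ValueError("K^-1 id order differs from the design animal order")
    q = design.Z.shape[1]
    if Kv.shape[0] != q:
        raise ValueError(f"K^-1 is {Kv.shape[0]}x{Kv.shape[0]} but design has {q} animals")
    if sigma_a2 <= 0 or sigma_e2 <= 0:
        raise ValueError("sigma_a2 and sigma_e2 must be positive")
    lam_a = sigma_e2 / sigma_a2
    m = design.W.shape[1]
    if m and (sigma_p2 is None or sigma_p2 <= 0):
        raise ValueError("permanent-environment term present but sigma_p2 not positive")
    lam_p = sigma_e2 / sigma_p2 if m else 0.0

    Xs = sp.csr_matrix(design.X)
    T = sp.hstack([Xs, design.Z, design.W]).tocsr()
    C = (T.T @ T).toarray()
    p = design.X.shape[1]
    sl_a = slice(p, p + q)
    sl_p = slice(p + q, p + q + m)
    Kd = Kv.toarray() if sp.issparse(Kv) else np.asarray(Kv, float)
    C[sl_a, sl_a] += lam_a * Kd
    if m:
        C[sl_p, sl_p] += lam_p * np.eye(m)
    rhs = T.T @ design.y
    layout = {"p": p, "q": q, "m": m, "sl_a": sl_a, "sl_p": sl_p, "T": T}
    return C, rhs, layout


def solve_mme(
    design: Design,
    K_inv,
    sigma_a2: float,
    sigma_e2: float,
    sigma_p2: float | None = None,
    compute_pev: bool = False,
) -> MMESolution:
    """Solve the MME; optionally return PEV/reliability per animal.

    ``K_inv`` may be a :class:`RelationshipMatrix` (id order checked), a
    dense array or a sparse matrix in the design's animal order.
    Reliability is ``1 - PEV / sigma_a^2``.
    """
    C, rhs, lay = assemble_mme(design, K_inv, sigma_a2, sigma_p2, sigma_e2)
    try:
        cf = la.cho_factor(C, lower=True, check_finite=False)
    except la.LinAlgError as exc:
        diag = np.diag(C)
        where = int(np.argmin(diag))
        raise np.linalg.LinAlgError(
            f"MME coefficient matrix singular (near row {where}); "
            "check for confounded fixed effects or a singular K"
        ) from exc
    sol = la.cho_solve(cf, rhs, check_finite=False)
    p, q, m = lay["p"], lay["q"], lay["m"]
    fixed = pd.Series(sol[:p], index=design.x_names, name="fixed")
    ebv = pd.Series(sol[lay["sl_a"]], index=design.animal_ids, name="ebv")
    pe = pd.Series(sol[lay["sl_p"]], index=design.pe_ids, name="pe")

    pev = reliability = None
    if compute_pev:
        from .reml import _spd_inverse_from_factor

        Cinv = _spd_inverse_from_factor(cf)
        pev_vals = sigma_e2 * np.diag(Cinv)[lay["sl_a"]]
        pev = pd.Series(pev_vals, index=design.animal_ids, name="pev")
        reliability = pd.Series(
            np.clip(1.0 - pev_vals / sigma_a2, 0.0, 1.0),
            index=design.animal_ids,
            name="reliability",
        )
    return MMESolution(
        fixed=fixed,
        ebv=ebv,
        pe=pe,
        pev=pev,
        reliability=reliability,
        sigma_a2=sigma_a2,
        sigma_p2=sigma_p2 if m else None,
        sigma_e2=sigma_e2,
    )


def predict_genetic_values(solution: MMESolution, ids: Sequence) -> pd.Series:
    """EBVs restricted to ``ids`` (which need no phenotypes of their own)."""
    ids = pd.Index(ids)
    missing = ids.difference(solution.ebv.index)
    if len(missing):
        raise KeyError(f"ids without breeding values: {list(missing[:10])}")
    return solution.ebv.loc[ids]
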