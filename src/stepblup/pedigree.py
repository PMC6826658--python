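"""Pedigree handling and pedigree-derived relationship machinery.

This module owns everything that can be computed from a pedigree alone:
validation and topological ordering, inbreeding coefficients (Meuwissen &
Luo style, without forming the dense numerator relationship matrix),
the tabular numerator relationship matrix A, Henderson's sparse direct
inverse A^-1 with Mendelian-sampling variances adjusted for inbreeding,
and the genotyped-animal submatrix A22 used by single-step evaluations.

Conventions
-----------
* Unknown parents are encoded with the sentinel ``0`` (also accepted:
  ``"0"``, ``""``, ``"."``, ``NaN``); internally they become index ``-1``.
* A pedigree is always stored topologically sorted: every parent precedes
  all of its offspring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.sparse as sp
import scipy.sparse.linalg as spla

__all__ = [
    "PedigreeError",
    "Pedigree",
    "RelationshipMatrix",
    "read_and_validate_pedigree",
    "inbreeding_coefficients",
    "build_A",
    "build_A_inverse",
    "extract_A22",
]

#: values interpreted as "parent unknown" when reading pedigree tables
UNKNOWN_SENTINELS = {0, "0", "", ".", None}


class PedigreeError(ValueError):
    """Raised for structurally invalid pedigrees (cycles, missing parents...)."""


@dataclass
class RelationshipMatrix:
    """A symmetric relationship matrix (or inverse) with its id index.

    Parameters
    ----------
    values
        Dense ``ndarray`` or scipy sparse matrix, symmetric.
    ids
        Animal identifiers, one per row/column, in matrix order.
    role
        One of ``A``, ``A_inverse``, ``A22``, ``G``, ``G_blended``,
        ``H_inverse`` — a tag describing what the matrix is.
    """

    values: np.ndarray | sp.spmatrix
    ids: pd.Index
    role: str

    def __post_init__(self) -> None:
        self.ids = pd.Index(self.ids)
        n = self.values.shape[0]
        if self.values.shape != (n, n) or n != len(self.ids):
            raise ValueError(
                f"matrix shape {self.values.shape} does not match {len(self.ids)} ids"
            )

    @property
    def n(self) -> int:
        return len(self.ids)

    def toarray(self) -> np.ndarray:
        if sp.issparse(self.values):
            return self.values.toarray()
        return np.asarray(self.values)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.toarray(), index=self.ids, columns=self.ids)

    def check_symmetric(self, tol: float = 1e-8) -> bool:
        a = self.values
        if sp.issparse(a):
            return abs(a - a.T).max() <= tol
        return bool(np.allclose(a, a.T, atol=tol))


@dataclass
class Pedigree:
    """A validated, topologically sorted pedigree.

    Attributes
    ----------
    frame
        DataFrame with columns ``id``, ``sire``, ``dam``, ``generation``
        (plus any extra metadata columns, e.g. ``sex`` from the simulator),
        sorted so parents precede offspring.
    sire_idx, dam_idx
        Integer positions of each animal's parents in ``frame`` order;
        ``-1`` means unknown.
    """

    frame: pd.DataFrame
    sire_idx: np.ndarray = field(repr=False)
    dam_idx: np.ndarray = field(repr=False)

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def ids(self) -> pd.Index:
        return pd.Index(self.frame["id"])

    @property
    def generations(self) -> np.ndarray:
        return self.frame["generation"].to_numpy()

    @property
    def n_founders(self) -> int:
        return int(np.sum((self.sire_idx < 0) & (self.dam_idx < 0)))

    def positions(self, ids: Iterable) -> np.ndarray:
        """Row positions of ``ids``; raises listing any unknown id."""
        idx = self.ids.get_indexer(pd.Index(ids))
        if (idx < 0).any():
            missing = list(pd.Index(ids)[idx < 0][:10])
            raise PedigreeError(f"ids not in pedigree: {missing}")
        return idx

    def subset_with_ancestors(self, ids: Iterable) -> "Pedigree":
        """Restrict to ``ids`` plus all of their ancestors (re-sorted)."""
        keep = np.zeros(self.n, dtype=bool)
        stack = list(self.positions(ids))
        while stack:
            i = stack.pop()
            if keep[i]:
                continue
            keep[i] = True
            for par in (self.sire_idx[i], self.dam_idx[i]):
                if par >= 0 and not keep[par]:
                    stack.append(par)
        sub = self.frame.loc[keep].copy()
        # parents outside the kept set are impossible by ancestor closure
        return read_and_validate_pedigree(sub)

    def summary(self) -> dict:
        return {
            "n_animals": self.n,
            "n_founders": self.n_founders,
            "n_generations": int(self.frame["generation"].nunique()),
            "max_generation": int(self.frame["generation"].max()),
        }


def _normalize_parent(col: pd.Series) -> pd.Series:
    vals = np.array(
        [None if (pd.isna(v) or v in UNKNOWN_SENTINELS) else v for v in col],
        dtype=object,
    )
    return pd.Series(vals, index=col.index, dtype=object)


def read_and_validate_pedigree(
    table: pd.DataFrame, allow_missing_parents: bool = False
) -> Pedigree:
    """Validate a pedigree table and return it topologically sorted.

    ``table`` needs columns ``id``, ``sire``, ``dam`` and optionally
    ``generation`` (derived as 1 + max parental generation if absent).
    Cycles (including self-parenting) raise :class:`PedigreeError` naming
    a cycle member. An id used both as sire and as dam triggers a warning
    in the returned report but is not fatal.
    """
    df = table.copy().reset_index(drop=True)
    required = {"id", "sire", "dam"}
    if not required.issubset(df.columns):
        raise PedigreeError(f"pedigree table must have columns {sorted(required)}")
    if df["id"].duplicated().any():
        dups = df.loc[df["id"].duplicated(), "id"].tolist()[:10]
        raise PedigreeError(f"duplicate animal ids: {dups}")

    df["sire"] = _normalize_parent(df["sire"])
    df["dam"] = _normalize_parent(df["dam"])

    known = set(df["id"])
    for col in ("sire", "dam"):
        missing = {v for v in df[col] if v is not None and v not in known}
        if missing:
            if allow_missing_parents:
                extra = pd.DataFrame(
                    {"id": sorted(missing, key=str), "sire": None, "dam": None}
                )
                df = pd.concat([extra, df], ignore_index=True)
                known |= missing
            else:
                raise PedigreeError(
                    f"{col}s absent from the id column: {sorted(missing, key=str)[:10]}"
                )

    sires = {v for v in df["sire"] if v is not None}
    dams = {v for v in df["dam"] if v is not None}
    both = sires & dams
    if both:
        import warnings

        warnings.warn(
            f"ids used both as sire and dam: {sorted(both, key=str)[:10]}",
            stacklevel=2,
        )

    # Kahn-style topological sort on the parent -> offspring DAG.
    pos = {a: i for i, a in enumerate(df["id"])}
    n = len(df)
    sire_i = np.array([pos.get(v, -1) if v is not None else -1 for v in df["sire"]])
    dam_i = np.array([pos.get(v, -1) if v is not None else -1 for v in df["dam"]])
    if ((sire_i == np.arange(n)) | (dam_i == np.arange(n))).any():
        bad = df.loc[(sire_i == np.arange(n)) | (dam_i == np.arange(n)), "id"].tolist()
        raise PedigreeError(f"animal listed as its own parent (cycle): {bad[:5]}")

    n_unplaced_parents = (sire_i >= 0).astype(int) + (dam_i >= 0).astype(int)
    children: list[list[int]] = [[] for _ in range(n)]
    for i in range(n):
        for par in (sire_i[i], dam_i[i]):
            if par >= 0:
                children[par].append(i)
    order: list[int] = [i for i in range(n) if n_unplaced_parents[i] == 0]
    head = 0
    counts = n_unplaced_parents.copy()
    while head < len(order):
        i = order[head]
        head += 1
        for c in children[i]:
            counts[c] -= 1
            if counts[c] == 0:
                order.append(c)
    if len(order) < n:
        cyc = df.loc[[i for i in range(n) if counts[i] > 0], "id"].tolist()
        raise PedigreeError(f"pedigree contains a cycle involving: {cyc[:10]}")

    df = df.iloc[order].reset_index(drop=True)
    pos = {a: i for i, a in enumerate(df["id"])}
    sire_idx = np.array([pos[v] if v is not None else -1 for v in df["sire"]])
    dam_idx = np.array([pos[v] if v is not None else -1 for v in df["dam"]])

    if "generation" not in df.columns or df["generation"].isna().any():
        gen = np.zeros(len(df), dtype=int)
        for i in range(len(df)):
            pg = [gen[p] for p in (sire_idx[i], dam_idx[i]) if p >= 0]
            gen[i] = 1 + max(pg) if pg else 0
        df["generation"] = gen
    df["generation"] = df["generation"].astype(int)

    return Pedigree(frame=df, sire_idx=sire_idx, dam_idx=dam_idx)


def inbreeding_coefficients(pedigree: Pedigree) -> pd.Series:
    """Per-animal inbreeding coefficients F without forming dense A.

    Uses the Meuwissen & Luo recursion: for each animal the sparse row of
    the gene-flow matrix L is accumulated ancestor by ancestor, giving
    ``A_ii = sum_j L_ij^2 d_j`` with Mendelian-sampling variances ``d_j``
    (founders d=1); ``F_i = A_ii - 1``.
    """
    n = pedigree.n
    s, d = pedigree.sire_idx, pedigree.dam_idx
    F = np.zeros(n)
    dvec = np.empty(n)
    for i in range(n):
        if s[i] >= 0 and d[i] >= 0:
            dvec[i] = 0.5 - 0.25 * (F[s[i]] + F[d[i]])
        elif s[i] >= 0 or d[i] >= 0:
            p = s[i] if s[i] >= 0 else d[i]
            dvec[i] = 0.75 - 0.25 * F[p]
        else:
            dvec[i] = 1.0
        # accumulate L_i. over ancestors, processing largest index first
        coeff: dict[int, float] = {i: 1.0}
        aii = 0.0
        while coeff:
            j = max(coeff)
            c = coeff.pop(j)
            aii += c * c * dvec[j] if j < i else c * c * dvec[i]
            for par in (s[j], d[j]):
                if par >= 0:
                    coeff[par] = coeff.get(par, 0.0) + 0.5 * c
        F[i] = aii - 1.0
    return pd.Series(F, index=pedigree.ids, name="F")


def build_A(pedigree: Pedigree, max_n: int = 20_000) -> RelationshipMatrix:
    """Dense numerator relationship matrix A by the tabular method.

    ``A(i, j) = 0.5 (A(j, s_i) + A(j, d_i))`` for earlier j, and
    ``A(i, i) = 1 + 0.5 A(s_i, d_i)``; unknown parents contribute zero.
    """
    n = pedigree.n
    if n > max_n:
        raise MemoryError(f"dense A for n={n} exceeds cap {max_n}")
    s, d = pedigree.sire_idx, pedigree.dam_idx
    A = np.zeros((n, n))
    for i in range(n):
        si, di = s[i], d[i]
        if si >= 0 and di >= 0:
            A[i, :i] = 0.5 * (A[si, :i] + A[di, :i])
            A[i, i] = 1.0 + 0.5 * A[si, di]
        elif si >= 0 or di >= 0:
            p = si if si >= 0 else di
            A[i, :i] = 0.5 * A[p, :i]
            A[i, i] = 1.0
        else:
            A[i, i] = 1.0
        A[:i, i] = A[i, :i]
    return RelationshipMatrix(A, pedigree.ids, role="A")


def build_A_inverse(
    pedigree: Pedigree, use_inbreeding: bool = True
) -> RelationshipMatrix:
    """Sparse A^-1 by Henderson's rules.

    Each animal contributes ``1/d_i`` times the pattern
    {(i,i): 1, (i,parent): -1/2, (parent,parent'): 1/4} over its known
    parents, where the Mendelian-sampling variance is
    ``d_i = 0.5 - 0.25 (F_s + F_d)`` with both parents known,
    ``0.75 - 0.25 F_p`` with one, and 1 for founders.  With
    ``use_inbreeding=False`` all F are treated as zero (the historical
    approximation, provided for comparison).
    """
    n = pedigree.n
    s, d = pedigree.sire_idx, pedigree.dam_idx
    F = (
        inbreeding_coefficients(pedigree).to_numpy()
        if use_inbreeding
        else np.zeros(n)
    )
    rows: list[int] = []
    cols: list[int] = []
    vals: list[float] = []

    def add(r: int, c: int, v: float) -> None:
        rows.append(r)
        cols.append(c)
        vals.append(v)

    for i in range(n):
        parents = [p for p in (s[i], d[i]) if p >= 0]
        if len(parents) == 2:
            di = 0.5 - 0.25 * (F[parents[0]] + F[parents[1]])
        elif len(parents) == 1:
            di = 0.75 - 0.25 * F[parents[0]]
        else:
            di = 1.0
        b = 1.0 / di
        add(i, i, b)
        for p in parents:
            add(i, p, -0.5 * b)
            add(p, i, -0.5 * b)
            for q in parents:
                add(p, q, 0.25 * b)
    Ainv = sp.coo_matrix((vals, (rows, cols)), shape=(n, n)).tocsc()
    return RelationshipMatrix(Ainv, pedigree.ids, role="A_inverse")


def extract_A22(
    source: Pedigree | RelationshipMatrix,
    genotyped_ids: Sequence,
    max_dense: int = 20_000,
) -> RelationshipMatrix:
    """Submatrix of A for the genotyped animals, in genotype order.

    Accepts either a dense A (sliced directly) or a pedigree.  From a
    pedigree, A22 is obtained without forming dense A when the pedigree
    exceeds ``max_dense``: the genotyped columns of A solve the sparse
    system ``A^-1 X = E`` with E the genotyped indicator columns.
    """
    gid = pd.Index(genotyped_ids)
    if isinstance(source, RelationshipMatrix):
        if source.role not in ("A",):
            raise ValueError(f"expected an A matrix, got role={source.role!r}")
        idx = source.ids.get_indexer(gid)
        if (idx < 0).any():
            raise PedigreeError(f"ids not in A: {list(gid[idx < 0][:10])}")
        sub = source.toarray()[np.ix_(idx, idx)]
        return RelationshipMatrix(sub, gid, role="A22")

    pedigree = source
    idx = pedigree.positions(gid)
    if pedigree.n <= max_dense:
        A = build_A(pedigree, max_n=max_dense).values
        return RelationshipMatrix(A[np.ix_(idx, idx)], gid, role="A22")
    Ainv = build_A_inverse(pedigree).values.tocsc()
    E = np.zeros((pedigree.n, len(idx)))
    E[idx, np.arange(len(idx))] = 1.0
    cols = spla.spsolve(Ainv, sp.csc_matrix(E)).toarray()
    sub = cols[idx, :]
    sub = 0.5 * (sub + sub.T)  # enforce symmetry against solver round-off
    return RelationshipMatrix(sub, gid, role="A22")
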