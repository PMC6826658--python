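"""Independent reference implementations used only as test oracles.

Each oracle deliberately follows a different computational route from
the package: Wright's path counting instead of the tabular recurrence,
dense GLS instead of the mixed-model equations, the block identity for
dense H instead of the sparse H^-1 assembly, and direct enumeration for
the exact Hardy-Weinberg test.
"""

from __future__ import annotations

from math import lgamma

import numpy as np

from stepblup.pedigree import Pedigree


def path_counting_A(ped: Pedigree) -> np.ndarray:
    """Numerator relationships by explicit path enumeration.

    a_xy sums (1/2)^(l1+l2) (1 + F_A) over all common ancestors A and
    pairs of ancestral paths from x and y to A that share only A;
    F_A is itself computed from the oracle, recursively.
    """
    n = ped.n
    s, d = ped.sire_idx, ped.dam_idx

    paths_cache: dict[int, list[tuple[int, ...]]] = {}

    def paths_up(x: int) -> list[tuple[int, ...]]:
        if x in paths_cache:
            return paths_cache[x]
        out = [(x,)]
        for par in (s[x], d[x]):
            if par >= 0:
                out += [(x,) + p for p in paths_up(par)]
        paths_cache[x] = out
        return out

    F_cache: dict[int, float] = {}

    def inbreeding(x: int) -> float:
        if x in F_cache:
            return F_cache[x]
        if s[x] < 0 or d[x] < 0:
            F_cache[x] = 0.0
        else:
            F_cache[x] = 0.5 * relationship(s[x], d[x])
        return F_cache[x]

    def relationship(x: int, y: int) -> float:
        if x == y:
            return 1.0 + inbreeding(x)
        total = 0.0
        for p1 in paths_up(x):
            set1 = set(p1[:-1])
            for p2 in paths_up(y):
                if p1[-1] != p2[-1]:
                    continue
                if set1 & set(p2[:-1]):
                    continue
                if p1[-1] in set1 or p1[-1] in set(p2[:-1]):
                    continue
                total += 0.5 ** (len(p1) + len(p2) - 2) * (1.0 + inbreeding(p1[-1]))
        return total

    A = np.empty((n, n))
    for i in range(n):
        for j in range(i, n):
            A[i, j] = A[j, i] = relationship(i, j)
    return A


def gls_blup(X, Z, W, y, K, sigma_a2, sigma_p2, sigma_e2):
    """Dense GLS/BLUP: b from GLS, a and p from the covariance identity."""
    import scipy.sparse as sp

    Zd = Z.toarray() if sp.issparse(Z) else np.asarray(Z, float)
    n = len(y)
    V = sigma_a2 * Zd @ K @ Zd.T + sigma_e2 * np.eye(n)
    Wd = None
    if W is not None and getattr(W, "shape", (0, 0))[1] > 0 and sigma_p2:
        Wd = W.toarray() if sp.issparse(W) else np.asarray(W, float)
        V += sigma_p2 * Wd @ Wd.T
    Vi = np.linalg.inv(V)
    b = np.linalg.solve(X.T @ Vi @ X, X.T @ Vi @ y)
    r = y - X @ b
    a = sigma_a2 * K @ Zd.T @ Vi @ r
    p = sigma_p2 * Wd.T @ Vi @ r if Wd is not None else np.zeros(0)
    return b, a, p


def dense_H(A: np.ndarray, geno_pos: np.ndarray, Gw: np.ndarray) -> np.ndarray:
    """Joint pedigree-genomic relationship matrix by the block identity.

    With animals partitioned into ungenotyped (1) and genotyped (2):
      H11 = A11 + A12 A22^-1 (Gw - A22) A22^-1 A21
      H12 = A12 A22^-1 Gw,   H22 = Gw.
    Returned in the original animal order.
    """
    n = A.shape[0]
    geno_pos = np.asarray(geno_pos)
    other = np.array([i for i in range(n) if i not in set(geno_pos)], dtype=int)
    A11 = A[np.ix_(other, other)]
    A12 = A[np.ix_(other, geno_pos)]
    A22 = A[np.ix_(geno_pos, geno_pos)]
    A22i = np.linalg.inv(A22)
    H = np.empty_like(A)
    H11 = A11 + A12 @ A22i @ (Gw - A22) @ A22i @ A12.T
    H12 = A12 @ A22i @ Gw
    H[np.ix_(other, other)] = H11
    H[np.ix_(other, geno_pos)] = H12
    H[np.ix_(geno_pos, other)] = H12.T
    H[np.ix_(geno_pos, geno_pos)] = Gw
    return H


def hwe_exact_enumeration(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact HWE p-value by direct evaluation of every configuration."""
    n = n_AA + n_Aa + n_aa
    n_rare = 2 * min(n_AA, n_aa) + n_Aa
    if n == 0 or n_rare == 0 or n_rare == 2 * n:
        return 1.0

    def logprob(h: int) -> float:
        rare_hom = (n_rare - h) // 2
        common_hom = n - h - rare_hom
        return (
            lgamma(n + 1)
            - lgamma(rare_hom + 1)
            - lgamma(h + 1)
            - lgamma(common_hom + 1)
            + h * np.log(2.0)
            + lgamma(n_rare + 1)
            + lgamma(2 * n - n_rare + 1)
            - lgamma(2 * n + 1)
        )

    hets = range(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    probs = {h: np.exp(logprob(h)) for h in hets}
    p_obs = probs[n_Aa]
    return min(1.0, sum(p for p in probs.values() if p <= p_obs * (1 + 1e-12)))


def random_pedigree(
    n_founders: int, n_offspring: int, seed: int, generations: int = 4
):
    """Small random pedigree frame for property tests (ids 1..n)."""
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = [(i + 1, 0, 0, 0) for i in range(n_founders)]
    males = [i + 1 for i in range(0, n_founders, 2)]
    females = [i + 1 for i in range(1, n_founders, 2)]
    next_id = n_founders + 1
    per_gen = max(2, n_offspring // max(1, generations - 1))
    for g in range(1, generations):
        for k in range(per_gen):
            sire = int(rng.choice(males))
            dam = int(rng.choice(females))
            rows.append((next_id, sire, dam, g))
            (males if k % 2 == 0 else females).append(next_id)
            next_id += 1
    return pd.DataFrame(rows, columns=["id", "sire", "dam", "generation"])
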