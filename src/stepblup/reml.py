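"""AI-REML variance-component estimation for the repeatability model.

Single-trait estimation of (sigma_a^2, sigma_p^2, sigma_e^2) and a
two-trait extension for genetic correlations.  The restricted likelihood

    -2 L = log|V| + log|X' V^-1 X| + y' P y + const,
    V = Z K Z' sigma_a^2 + W W' sigma_p^2 + I sigma_e^2,
    P = V^-1 - V^-1 X (X' V^-1 X)^-1 X' V^-1

is never evaluated through dense V above a size threshold; instead all
quantities come from mixed-model-equation identities.  With the full
(R^-1-weighted) coefficient matrix C and T = [X Z W],

    -2 L = n log sigma_e^2 + q log sigma_a^2 + log|K| + m log sigma_p^2
           + log|C| + y' P y,
    y' P y = (y'y - u_hat' T'y) / sigma_e^2,

and the traces needed for the scores follow from inverse blocks of C:

    tr(P Z K Z') = q / sa - tr(C^aa K^-1) / sa^2
    tr(P W W')   = m / sp - tr(C^pp) / sp^2
    tr(P)        = (n - rank X - sa tr(PZKZ') - sp tr(PWW')) / se.

Updates are Newton steps with the average-information matrix
AI_ij = y' P V_i P V_j P y / 2, falling back to EM-REML whenever an AI
step leaves the parameter space or decreases the likelihood.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg as la
import scipy.sparse as sp
import scipy.sparse.linalg as spla

from .mme import Design
from .pedigree import RelationshipMatrix

__all__ = [
    "VarianceComponents",
    "GeneticCovarianceEstimate",
    "ConvergenceError",
    "reml_loglik",
    "ai_reml",
    "ai_reml_bivariate",
]


class ConvergenceError(RuntimeError):
    """AI-REML failed to converge; carries the iteration trajectory."""

    def __init__(self, message: str, trajectory: list):
        super().__init__(message)
        self.trajectory = trajectory


@dataclass
class VarianceComponents:
    """Estimated variance components of the repeatability model."""

    sigma_a2: float
    sigma_p2: float | None
    sigma_e2: float
    se_sigma_a2: float | None = None
    se_sigma_p2: float | None = None
    se_sigma_e2: float | None = None
    h2: float = 0.0
    h2_se: float | None = None
    repeatability: float | None = None
    repeatability_se: float | None = None
    n_iterations: int = 0
    loglik: float = 0.0
    converged: bool = True
    boundary: bool = False
    trajectory: list = field(default_factory=list, repr=False)

    @property
    def total(self) -> float:
        return self.sigma_a2 + (self.sigma_p2 or 0.0) + self.sigma_e2

    def to_dict(self) -> dict:
        return {
            "sigma_a2": self.sigma_a2,
            "sigma_p2": self.sigma_p2,
            "sigma_e2": self.sigma_e2,
            "h2": self.h2,
            "h2_se": self.h2_se,
            "repeatability": self.repeatability,
            "repeatability_se": self.repeatability_se,
            "n_iterations": self.n_iterations,
            "loglik": self.loglik,
            "converged": self.converged,
            "boundary": self.boundary,
        }


@dataclass
class GeneticCovarianceEstimate:
    """Bivariate REML estimate: 2x2 covariance matrices per component."""

    sigma_a: np.ndarray
    sigma_p: np.ndarray
    sigma_e: np.ndarray
    genetic_correlation: float
    genetic_correlation_se: float | None
    n_iterations: int
    loglik: float
    converged: bool
    theta_cov: np.ndarray | None = None

    def to_dict(self) -> dict:
        return {
            "sigma_a": self.sigma_a.tolist(),
            "sigma_p": self.sigma_p.tolist(),
            "sigma_e": self.sigma_e.tolist(),
            "genetic_correlation": self.genetic_correlation,
            "genetic_correlation_se": self.genetic_correlation_se,
            "n_iterations": self.n_iterations,
            "loglik": self.loglik,
            "converged": self.converged,
        }


# ---------------------------------------------------------------------------
# shared helpers


def _spd_inverse_from_factor(cf) -> np.ndarray:
    """Full inverse from a scipy cho_factor, via LAPACK dpotri (n^3/3)."""
    c, lower = cf
    inv, info = la.lapack.dpotri(c, lower=lower)
    if info != 0:
        raise la.LinAlgError(f"dpotri failed with info={info}")
    # dpotri fills only one triangle; mirror it
    if lower:
        return np.tril(inv) + np.tril(inv, -1).T
    return np.triu(inv) + np.triu(inv, 1).T


def _lower_factor_inverse(cf) -> np.ndarray:
    """L^-1 (lower triangular) from a lower cho_factor, via LAPACK dtrtri."""
    c, lower = cf
    if not lower:
        raise ValueError("expected a lower Cholesky factor")
    linv, info = la.lapack.dtrtri(c, lower=True)
    if info != 0:
        raise la.LinAlgError(f"dtrtri failed with info={info}")
    return np.tril(linv)


def _cinv_diag(Linv: np.ndarray) -> np.ndarray:
    """diag(C^-1) from L^-1 where C = L L'."""
    return np.einsum("ij,ij->j", Linv, Linv)


def _cinv_entries(
    Linv: np.ndarray, rows: np.ndarray, cols: np.ndarray, chunk: int = 4096
) -> np.ndarray:
    """Selected entries C^-1[rows, cols] = col_r(L^-1) . col_c(L^-1)."""
    out = np.empty(len(rows))
    for start in range(0, len(rows), chunk):
        r = rows[start : start + chunk]
        c = cols[start : start + chunk]
        out[start : start + chunk] = np.einsum(
            "ij,ij->j", Linv[:, r], Linv[:, c]
        )
    return out


def _logdet_spd(mat) -> float:
    if sp.issparse(mat):
        lu = spla.splu(mat.tocsc(), permc_spec="MMD_AT_PLUS_A", diag_pivot_thresh=0.0)
        d = lu.U.diagonal()
        if (d <= 0).any():
            sign, val = np.linalg.slogdet(mat.toarray())
            if sign <= 0:
                raise np.linalg.LinAlgError("matrix is not positive definite")
            return float(val)
        return float(np.sum(np.log(d)))
    sign, val = np.linalg.slogdet(np.asarray(mat))
    if sign <= 0:
        raise np.linalg.LinAlgError("matrix is not positive definite")
    return float(val)


def _trace_product(block: np.ndarray, B) -> float:
    """tr(block @ B) for symmetric B, exploiting sparsity of B."""
    if sp.issparse(B):
        Bc = B.tocoo()
        return float(np.sum(block[Bc.col, Bc.row] * Bc.data))
    return float(np.sum(block * np.asarray(B).T))


def _kinv_dense(K_inv) -> np.ndarray | sp.spmatrix:
    if isinstance(K_inv, RelationshipMatrix):
        return K_inv.values
    return K_inv


def _full_rank_columns(X: np.ndarray) -> np.ndarray:
    """Drop linearly dependent columns (rank-revealing QR, pivoted).

    The restricted likelihood depends on X only through its column
    space, so redundant columns are removed rather than allowed to make
    the equations singular.
    """
    X = np.asarray(X, float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X must have at least one column")
    _, R, piv = la.qr(X, mode="economic", pivoting=True)
    diag = np.abs(np.diag(R))
    tol = diag.max() * max(X.shape) * np.finfo(float).eps if diag.size else 0.0
    rank = int(np.sum(diag > tol))
    keep = np.sort(piv[:rank])
    return X[:, keep]


# ---------------------------------------------------------------------------
# restricted log-likelihood


def reml_loglik(
    y: np.ndarray,
    X: np.ndarray,
    Z: sp.spmatrix,
    W: sp.spmatrix | None,
    theta,
    K: np.ndarray | None = None,
    K_inv=None,
    method: str = "auto",
) -> float:
    """Restricted log-likelihood (-0.5 * the -2L above, constant dropped).

    ``theta = (sigma_a2, sigma_p2, sigma_e2)``; pass ``sigma_p2=None`` (or
    ``W=None``) for a model without the permanent-environment term.
    ``method='dense'`` evaluates the textbook formula through dense V
    (small n only); ``'mme'`` uses the coefficient-matrix identities; the
    default picks dense below 500 records.
    """
    y = np.asarray(y, float)
    n = len(y)
    sa, sp2, se = theta
    if method == "auto":
        method = "dense" if n <= 500 else "mme"
    if method == "dense":
        if K is None:
            Kinv = _kinv_dense(K_inv)
            K = np.linalg.inv(Kinv.toarray() if sp.issparse(Kinv) else np.asarray(Kinv))
        Zd = Z.toarray() if sp.issparse(Z) else np.asarray(Z)
        V = sa * Zd @ K @ Zd.T + se * np.eye(n)
        if W is not None and sp2 is not None and W.shape[1] > 0:
            Wd = W.toarray() if sp.issparse(W) else np.asarray(W)
            V += sp2 * Wd @ Wd.T
        X = _full_rank_columns(X)
        Vi = np.linalg.inv(V)
        XtViX = X.T @ Vi @ X
        beta = np.linalg.solve(XtViX, X.T @ Vi @ y)
        r = y - X @ beta
        neg2 = _logdet_spd(V) + _logdet_spd(XtViX) + float(r @ Vi @ r)
        return -0.5 * neg2
    if method != "mme":
        raise ValueError(f"unknown method {method!r}")
    state = _SingleTraitREML(y, X, Z, W, K_inv)._evaluate((sa, sp2, se))
    return -0.5 * state["neg2"]


# ---------------------------------------------------------------------------
# single trait


class _SingleTraitREML:
    """MME-based evaluation of likelihood, scores and AI for one trait."""

    def __init__(self, y, X, Z, W, K_inv):
        self.y = np.asarray(y, float)
        self.X = _full_rank_columns(X)
        self.Z = sp.csr_matrix(Z)
        self.has_pe = W is not None and W.shape[1] > 0
        self.W = sp.csr_matrix(W) if self.has_pe else sp.csr_matrix((len(self.y), 0))
        Kinv = _kinv_dense(K_inv)
        self.Kinv = Kinv.tocsc() if sp.issparse(Kinv) else np.asarray(Kinv, float)
        self.Kinv_d = self.Kinv.toarray() if sp.issparse(self.Kinv) else self.Kinv
        self.n = len(self.y)
        self.p = self.X.shape[1]
        self.q = self.Z.shape[1]
        self.m = self.W.shape[1]
        Xs = sp.csr_matrix(self.X)
        self.T = sp.hstack([Xs, self.Z, self.W]).tocsr()
        self.TtT = (self.T.T @ self.T).toarray()
        self.Tty = self.T.T @ self.y
        self.yty = float(self.y @ self.y)
        self.logdetK = -_logdet_spd(self.Kinv)
        self.sl_a = slice(self.p, self.p + self.q)
        self.sl_p = slice(self.p + self.q, self.p + self.q + self.m)
        if sp.issparse(self.Kinv):
            kc = self.Kinv.tocoo()
            self._k_rows = kc.row + self.p
            self._k_cols = kc.col + self.p
            self._k_vals = kc.data
        else:
            self._k_rows = None

    def _evaluate(self, theta, want_traces: bool = False) -> dict:
        sa, sp2, se = theta
        C = self.TtT / se
        C[self.sl_a, self.sl_a] += self.Kinv_d / sa
        if self.m:
            idx = np.arange(self.p + self.q, self.p + self.q + self.m)
            C[idx, idx] += 1.0 / sp2
        cf = la.cho_factor(C, lower=True, check_finite=False)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        u = la.cho_solve(cf, self.Tty / se, check_finite=False)
        ypy = (self.yty - float(u @ self.Tty)) / se
        neg2 = (
            self.n * np.log(se)
            + self.q * np.log(sa)
            + self.logdetK
            + (self.m * np.log(sp2) if self.m else 0.0)
            + logdetC
            + ypy
        )
        out = {"neg2": neg2, "u": u, "ypy": ypy, "cf": cf}
        if want_traces:
            Linv = _lower_factor_inverse(cf)
            # tr(C^aa K^-1) through selected inverse entries on the K^-1
            # pattern; tr(C^pp) from the inverse diagonal
            if self._k_rows is not None:
                vals = _cinv_entries(Linv, self._k_rows, self._k_cols)
                out["tr_CaaKinv"] = float(vals @ self._k_vals)
                if self.m:
                    dpe = _cinv_diag(Linv[:, self.sl_p])
                    out["tr_Cpp"] = float(dpe.sum())
            else:
                cols = Linv[:, self.sl_a]
                Caa = cols.T @ cols
                out["tr_CaaKinv"] = float(np.sum(Caa * self.Kinv_d))
                if self.m:
                    out["tr_Cpp"] = float(_cinv_diag(Linv[:, self.sl_p]).sum())
        return out

    def em_and_scores(self, theta, state) -> dict:
        sa, sp2, se = theta
        u = state["u"]
        a_hat = u[self.sl_a]
        p_hat = u[self.sl_p]
        e_hat = self.y - self.T @ u
        tr_CaaKinv = state["tr_CaaKinv"]
        qa = float(a_hat @ (self.Kinv @ a_hat))
        tr_PZKZt = self.q / sa - tr_CaaKinv / sa**2
        res = {
            "a_hat": a_hat,
            "p_hat": p_hat,
            "e_hat": e_hat,
            "qa": qa,
            "tr_CaaKinv": tr_CaaKinv,
        }
        score_a = -0.5 * (tr_PZKZt - qa / sa**2)
        if self.m:
            tr_Cpp = state["tr_Cpp"]
            qp = float(p_hat @ p_hat)
            tr_PWWt = self.m / sp2 - tr_Cpp / sp2**2
            score_p = -0.5 * (tr_PWWt - qp / sp2**2)
            res.update(qp=qp, tr_Cpp=tr_Cpp)
        else:
            tr_PWWt, score_p = 0.0, None
        trP = (
            self.n - self.p - sa * tr_PZKZt - (sp2 * tr_PWWt if self.m else 0.0)
        ) / se
        ee = float(e_hat @ e_hat)
        score_e = -0.5 * (trP - ee / se**2)
        res["scores"] = np.array(
            [score_a, score_p, score_e] if self.m else [score_a, score_e]
        )
        # EM-REML updates (never decrease the restricted likelihood)
        em_a = (qa + tr_CaaKinv) / self.q
        em_e = se * state["ypy"] / (self.n - self.p)
        if self.m:
            em_p = (res["qp"] + res["tr_Cpp"]) / self.m
            res["em"] = np.array([em_a, em_p, em_e])
        else:
            res["em"] = np.array([em_a, em_e])
        return res

    def ai_matrix(self, theta, state, extras) -> np.ndarray:
        sa, sp2, se = theta
        fs = [self.Z @ (extras["a_hat"] / sa)]
        if self.m:
            fs.append(self.W @ (extras["p_hat"] / sp2))
        fs.append(extras["e_hat"] / se)
        cf = state["cf"]
        pfs = []
        for f in fs:
            uf = la.cho_solve(cf, (self.T.T @ f) / se, check_finite=False)
            pfs.append((f - self.T @ uf) / se)
        k = len(fs)
        AI = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(fs[i] @ pfs[j])
        return AI


def ai_reml(
    y,
    X,
    Z,
    W,
    K_inv,
    init: tuple | None = None,
    max_iter: int = 100,
    tol_param: float = 1e-8,
    tol_loglik: float = 1e-9,
    verbose: bool = False,
) -> VarianceComponents:
    """Estimate (sigma_a^2[, sigma_p^2], sigma_e^2) by AI-REML.

    ``W=None`` (or zero columns) drops the permanent-environment
    component.  Default initialisation splits var(y) as 0.3 / 0.2 / 0.5
    over the genetic, permanent-environment and residual parts.
    Estimates are floored at ``1e-8 var(y)``; a floored component is
    flagged ``boundary`` and its SE marked unreliable (NaN).
    """
    engine = _SingleTraitREML(y, X, Z, W, K_inv)
    vy = float(np.var(np.asarray(y, float)))
    has_pe = engine.m > 0
    if init is None:
        theta = np.array([0.3 * vy, 0.2 * vy, 0.5 * vy] if has_pe else [0.4 * vy, 0.6 * vy])
    else:
        theta = np.array([v for v in init if v is not None], float)
        if np.any(theta <= 0):
            raise ValueError("initial variance components must be strictly positive")
    floor = 1e-8 * vy
    k = len(theta)

    def unpack(t):
        return (t[0], t[1] if has_pe else None, t[-1])

    state = engine._evaluate(unpack(theta), want_traces=True)
    trajectory = [{"theta": theta.copy(), "neg2": state["neg2"], "step": "init"}]
    converged = False
    AI = None
    for it in range(1, max_iter + 1):
        extras = engine.em_and_scores(unpack(theta), state)
        AI = engine.ai_matrix(unpack(theta), state, extras)
        step_kind = "AI"
        # active set: start from components pinned at the floor with a
        # negative score (their AI rows blow up as 1/theta^2); whenever a
        # joint Newton step drives a component below the floor, pin it
        # there and re-solve for the rest.
        free = (theta > 10 * floor) | (extras["scores"] > 0)
        cand = None
        try:
            for _ in range(k):
                idx = np.flatnonzero(free)
                if len(idx) == 0:
                    break
                delta = np.zeros(k)
                delta[idx] = la.solve(
                    AI[np.ix_(idx, idx)], extras["scores"][idx], assume_a="sym"
                )
                trial = theta + delta
                trial[~free] = np.minimum(theta[~free], floor)
                violating = free & (trial < floor)
                if not violating.any():
                    cand = np.maximum(trial, floor)
                    break
                free = free & ~violating
        except la.LinAlgError:
            cand = None
        if cand is None:
            cand = np.maximum(extras["em"], floor)
            step_kind = "EM"
        new_state = None
        try:
            new_state = engine._evaluate(unpack(cand), want_traces=True)
        except la.LinAlgError:
            pass
        if step_kind == "AI" and (
            new_state is None or new_state["neg2"] > state["neg2"] + 1e-10
        ):
            cand = np.maximum(extras["em"], floor)
            step_kind = "EM"
            new_state = engine._evaluate(unpack(cand), want_traces=True)
        if new_state is None:  # EM step itself failed: give up
            raise ConvergenceError("likelihood evaluation failed", trajectory)
        # components pinned at the floor are excluded from the relative
        # change criterion (they no longer move meaningfully)
        active = (theta > 10 * floor) | (cand > 10 * floor)
        rel = (
            np.max(np.abs(cand - theta)[active] / np.maximum(theta[active], floor))
            if active.any()
            else 0.0
        )
        dll = state["neg2"] - new_state["neg2"]
        theta, state = cand, new_state
        trajectory.append({"theta": theta.copy(), "neg2": state["neg2"], "step": step_kind})
        if verbose:
            print(f"iter {it:3d} [{step_kind}] -2L={state['neg2']:.6f} theta={theta}")
        if rel < tol_param or abs(dll) < tol_loglik:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"AI-REML did not converge in {max_iter} iterations", trajectory
        )

    boundary = bool(np.any(theta <= 100 * floor))
    if boundary:
        warnings.warn(
            "a variance component converged to the boundary; its SE is unreliable",
            stacklevel=2,
        )
    extras = engine.em_and_scores(unpack(theta), state)
    AI = engine.ai_matrix(unpack(theta), state, extras)
    try:
        cov = la.inv(AI)
        ses = np.sqrt(np.maximum(np.diag(cov), 0.0))
    except la.LinAlgError:
        cov = np.full((k, k), np.nan)
        ses = np.full(k, np.nan)
    if boundary:
        ses = np.where(theta <= 100 * floor, np.nan, ses)

    sa = float(theta[0])
    sp2 = float(theta[1]) if has_pe else None
    se_r = float(theta[-1])
    tot = sa + (sp2 or 0.0) + se_r
    h2 = sa / tot
    rep = (sa + (sp2 or 0.0)) / tot if has_pe else None

    def _delta_se(grad):
        if np.isnan(cov).any():
            return None
        return float(np.sqrt(max(grad @ cov @ grad, 0.0)))

    if has_pe:
        g_h2 = np.array([(tot - sa) / tot**2, -sa / tot**2, -sa / tot**2])
        g_r = np.array(
            [(tot - sa - sp2) / tot**2, (tot - sa - sp2) / tot**2, -(sa + sp2) / tot**2]
        )
        rep_se = _delta_se(g_r)
    else:
        g_h2 = np.array([(tot - sa) / tot**2, -sa / tot**2])
        rep_se = None
    return VarianceComponents(
        sigma_a2=sa,
        sigma_p2=sp2,
        sigma_e2=se_r,
        se_sigma_a2=float(ses[0]),
        se_sigma_p2=float(ses[1]) if has_pe else None,
        se_sigma_e2=float(ses[-1]),
        h2=h2,
        h2_se=_delta_se(g_h2),
        repeatability=rep,
        repeatability_se=rep_se,
        n_iterations=len(trajectory) - 1,
        loglik=-0.5 * state["neg2"],
        converged=converged,
        boundary=boundary,
        trajectory=trajectory,
    )


# ---------------------------------------------------------------------------
# bivariate


def _sym_bases() -> list[tuple[int, int]]:
    return [(0, 0), (1, 0), (1, 1)]


def _basis_matrix(i: int, j: int) -> np.ndarray:
    E = np.zeros((2, 2))
    E[i, j] = 1.0
    E[j, i] = 1.0
    return E


def _project_psd(mat: np.ndarray, floor: float) -> tuple[np.ndarray, bool]:
    w, v = np.linalg.eigh(0.5 * (mat + mat.T))
    if w.min() >= floor:
        return mat, False
    w = np.maximum(w, floor)
    return (v * w) @ v.T, True


class _BivariateREML:
    """AI-REML over 9 parameters (2x2 Sigma_a, Sigma_p, Sigma_e).

    Both traits share the design (every record carries both trait
    values), so the coefficient matrix has Kronecker trait structure.
    """

    def __init__(self, Y, X, Z, W, K_inv):
        self.Y = np.asarray(Y, float)  # n x 2
        if self.Y.ndim != 2 or self.Y.shape[1] != 2:
            raise ValueError("Y must be n x 2")
        self.X = _full_rank_columns(X)
        self.Z = sp.csr_matrix(Z)
        self.W = sp.csr_matrix(W)
        if self.W.shape[1] == 0:
            raise ValueError("bivariate model requires the permanent-environment term")
        Kinv = _kinv_dense(K_inv)
        self.Kinv = Kinv.tocsc() if sp.issparse(Kinv) else np.asarray(Kinv, float)
        self.Kinv_d = self.Kinv.toarray() if sp.issparse(self.Kinv) else self.Kinv
        self.n = self.Y.shape[0]
        self.p = self.X.shape[1]
        self.q = self.Z.shape[1]
        self.m = self.W.shape[1]
        Xs = sp.csr_matrix(self.X)
        self.T = sp.hstack([Xs, self.Z, self.W]).tocsr()
        self.TtT = (self.T.T @ self.T).toarray()
        self.TtY = np.column_stack([self.T.T @ self.Y[:, t] for t in (0, 1)])
        self.YtY = self.Y.T @ self.Y
        self.logdetK = -_logdet_spd(self.Kinv)
        self.dim = self.p + self.q + self.m
        self.sl_a = slice(self.p, self.p + self.q)
        self.sl_p = slice(self.p + self.q, self.dim)

    def _slices(self, t: int):
        off = t * self.dim
        return (
            slice(off, off + self.p),
            slice(off + self.p, off + self.p + self.q),
            slice(off + self.p + self.q, off + self.dim),
        )

    def evaluate(self, Sa, Sp, Se) -> dict:
        R0inv = la.inv(Se)
        Sainv = la.inv(Sa)
        Spinv = la.inv(Sp)
        d2 = 2 * self.dim
        C = np.kron(R0inv, self.TtT)
        for s in range(2):
            _, a_s, p_s = self._slices(s)
            for t in range(2):
                _, a_t, p_t = self._slices(t)
                C[a_s, a_t] += Sainv[s, t] * self.Kinv_d
                ii = np.arange(p_s.start, p_s.stop)
                jj = np.arange(p_t.start, p_t.stop)
                C[ii, jj] += Spinv[s, t]
        rhs = np.concatenate(
            [self.TtY @ R0inv[s] for s in range(2)]
        )
        cf = la.cho_factor(C, lower=True, check_finite=False)
        logdetC = 2.0 * float(np.sum(np.log(np.diag(cf[0]))))
        u = la.cho_solve(cf, rhs, check_finite=False)
        ypy = float(np.sum(R0inv * self.YtY)) - float(u @ rhs)
        neg2 = (
            self.n * _logdet_spd(Se)
            + self.q * _logdet_spd(Sa)
            + 2.0 * self.logdetK
            + self.m * _logdet_spd(Sp)
            + logdetC
            + ypy
        )
        return {"neg2": neg2, "u": u, "cf": cf, "R0inv": R0inv, "Sainv": Sainv,
                "Spinv": Spinv, "rhs": rhs}

    def scores_and_ai(self, Sa, Sp, Se, state) -> tuple[np.ndarray, np.ndarray]:
        u = state["u"]
        cf = state["cf"]
        R0inv, Sainv, Spinv = state["R0inv"], state["Sainv"], state["Spinv"]
        Cinv = _spd_inverse_from_factor(cf)

        a_hat = [u[self._slices(t)[1]] for t in range(2)]
        p_hat = [u[self._slices(t)[2]] for t in range(2)]
        e_hat = [
            self.Y[:, t] - self.T @ u[t * self.dim : (t + 1) * self.dim]
            for t in range(2)
        ]
        # quadratic-form and trace building blocks per trait pair
        Qa = np.array([[a_hat[s] @ (self.Kinv @ a_hat[t]) for t in range(2)] for s in range(2)])
        Qp = np.array([[p_hat[s] @ p_hat[t] for t in range(2)] for s in range(2)])
        Qe = np.array([[e_hat[s] @ e_hat[t] for t in range(2)] for s in range(2)])
        TrA = np.empty((2, 2))
        TrP = np.empty((2, 2))
        TrE = np.empty((2, 2))
        for s in range(2):
            _, a_s, p_s = self._slices(s)
            blk_s = slice(s * self.dim, (s + 1) * self.dim)
            for t in range(2):
                _, a_t, p_t = self._slices(t)
                blk_t = slice(t * self.dim, (t + 1) * self.dim)
                TrA[s, t] = _trace_product(Cinv[a_s, a_t], self.Kinv)
                TrP[s, t] = float(np.trace(Cinv[p_s, p_t]))
                TrE[s, t] = float(np.sum(Cinv[blk_s, blk_t] * self.TtT.T))

        params = []
        scores = []
        fvecs = []
        for grp, S_inv, Qmat, Trmat, count in (
            ("a", Sainv, Qa, TrA, self.q),
            ("p", Spinv, Qp, TrP, self.m),
            ("e", R0inv, Qe, TrE, self.n),
        ):
            for (i, j) in _sym_bases():
                E = _basis_matrix(i, j)
                F = S_inv @ E @ S_inv
                quad = float(np.sum(F * Qmat))
                if grp == "e":
                    trace = self.n * float(np.trace(R0inv @ E)) - float(np.sum(F * TrE))
                else:
                    trace = count * float(np.trace(E @ S_inv)) - float(np.sum(F * Trmat))
                scores.append(-0.5 * (trace - quad))
                params.append((grp, i, j))
                # f = V-dot P y per parameter
                if grp == "a":
                    M = E @ Sainv
                    f = np.column_stack(
                        [self.Z @ (M[s, 0] * a_hat[0] + M[s, 1] * a_hat[1]) for s in range(2)]
                    )
                elif grp == "p":
                    M = E @ Spinv
                    f = np.column_stack(
                        [self.W @ (M[s, 0] * p_hat[0] + M[s, 1] * p_hat[1]) for s in range(2)]
                    )
                else:
                    M = E @ R0inv
                    f = np.column_stack(
                        [M[s, 0] * e_hat[0] + M[s, 1] * e_hat[1] for s in range(2)]
                    )
                fvecs.append(f)

        pfs = []
        for f in fvecs:
            fr = f @ R0inv  # R-tilde^-1 f, trait columns
            rhs_f = np.concatenate([self.T.T @ fr[:, s] for s in range(2)])
            uf = la.cho_solve(cf, rhs_f, check_finite=False)
            resid = np.column_stack(
                [f[:, s] - self.T @ uf[slice(s * self.dim, (s + 1) * self.dim)] for s in range(2)]
            )
            pfs.append(resid @ R0inv)
        k = len(fvecs)
        AI = np.empty((k, k))
        for i in range(k):
            for j in range(i, k):
                AI[i, j] = AI[j, i] = 0.5 * float(np.sum(fvecs[i] * pfs[j]))
        return np.array(scores), AI


def _theta_to_mats(theta: np.ndarray) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    def m(v):
        return np.array([[v[0], v[1]], [v[1], v[2]]])

    return m(theta[0:3]), m(theta[3:6]), m(theta[6:9])


def _mats_to_theta(Sa, Sp, Se) -> np.ndarray:
    return np.array(
        [Sa[0, 0], Sa[1, 0], Sa[1, 1], Sp[0, 0], Sp[1, 0], Sp[1, 1],
         Se[0, 0], Se[1, 0], Se[1, 1]]
    )


def ai_reml_bivariate(
    Y,
    X,
    Z,
    W,
    K_inv,
    init: tuple[np.ndarray, np.ndarray, np.ndarray] | None = None,
    max_iter: int = 100,
    tol_param: float = 1e-6,
    tol_loglik: float = 1e-8,
    verbose: bool = False,
    fix_covariances: bool = False,
) -> GeneticCovarianceEstimate:
    """Two-trait AI-REML; returns the genetic correlation with its SE.

    ``Y`` is the n x 2 matrix of trait values on shared records; the
    design (X, Z, W) is common to both traits.  Updates project each 2x2
    component matrix back to the PSD cone (with a warning) and step-halve
    when a full AI step decreases the restricted likelihood.  With
    ``fix_covariances`` all cross-trait covariances are held at zero
    (the model then factorises into the two single-trait models).
    """
    engine = _BivariateREML(Y, X, Z, W, K_inv)
    vy = np.var(engine.Y, axis=0)
    ry = float(np.corrcoef(engine.Y[:, 0], engine.Y[:, 1])[0, 1])
    if init is None:
        def mk(scale):
            d = scale * vy
            off = 0.5 * ry * np.sqrt(d[0] * d[1])
            return np.array([[d[0], off], [off, d[1]]])

        Sa, Sp, Se = mk(0.3), mk(0.2), np.diag(0.5 * vy)
    else:
        Sa, Sp, Se = (np.asarray(m, float).copy() for m in init)
    _cov_idx = [1, 4, 7]  # positions of the three cross-trait covariances
    if fix_covariances:
        for m_ in (Sa, Sp, Se):
            m_[0, 1] = m_[1, 0] = 0.0
    floor = 1e-8 * float(np.mean(vy))

    state = engine.evaluate(Sa, Sp, Se)
    theta = _mats_to_theta(Sa, Sp, Se)
    converged = False
    n_iter = 0
    cov_theta = None
    for it in range(1, max_iter + 1):
        n_iter = it
        scores, AI = engine.scores_and_ai(Sa, Sp, Se, state)
        diag_idx = {0, 2, 3, 5, 6, 8}
        free = [
            i
            for i in range(9)
            if not (fix_covariances and i in _cov_idx)
            and not (
                # variances pinned at the floor with no pull to re-enter
                i in diag_idx
                and theta[i] <= 10 * floor
                and scores[i] <= 0
            )
        ]
        delta = np.zeros(9)
        try:
            delta[free] = la.solve(
                AI[np.ix_(free, free)], scores[free], assume_a="sym"
            )
        except la.LinAlgError:
            delta[free] = scores[free] / max(np.abs(np.diag(AI)).max(), 1.0)
        # trust region: no variance moves by more than 80% in one trial
        scale_ref = np.maximum(np.abs(theta), 0.05 * float(np.mean(vy)))
        overshoot = np.max(np.abs(delta) / scale_ref)
        if overshoot > 0.8:
            delta *= 0.8 / overshoot
        accepted = False
        step = 1.0
        for _ in range(25):
            cand = theta + step * delta
            Sa_c, Sp_c, Se_c = _theta_to_mats(cand)
            proj = False
            Sa_c, p1 = _project_psd(Sa_c, floor)
            Sp_c, p2 = _project_psd(Sp_c, floor)
            Se_c, p3 = _project_psd(Se_c, floor)
            proj = p1 or p2 or p3
            try:
                new_state = engine.evaluate(Sa_c, Sp_c, Se_c)
            except (la.LinAlgError, np.linalg.LinAlgError):
                step *= 0.5
                continue
            if new_state["neg2"] <= state["neg2"] + 1e-8:
                if proj:
                    warnings.warn(
                        "bivariate REML update projected to the PSD cone", stacklevel=2
                    )
                accepted = True
                break
            step *= 0.5
        if not accepted:
            # cannot improve: treat as converged at the current point
            converged = True
            break
        new_theta = _mats_to_theta(Sa_c, Sp_c, Se_c)
        rel = np.max(np.abs(new_theta - theta) / np.maximum(np.abs(theta), floor))
        dll = state["neg2"] - new_state["neg2"]
        Sa, Sp, Se = Sa_c, Sp_c, Se_c
        theta, state = new_theta, new_state
        if verbose:
            print(f"iter {it:3d} -2L={state['neg2']:.6f} rg="
                  f"{Sa[0,1]/np.sqrt(Sa[0,0]*Sa[1,1]):.4f}")
        if rel < tol_param or abs(dll) < tol_loglik:
            converged = True
            break

    scores, AI = engine.scores_and_ai(Sa, Sp, Se, state)
    try:
        cov_theta = la.inv(AI)
    except la.LinAlgError:
        cov_theta = None
    rg = float(Sa[0, 1] / np.sqrt(Sa[0, 0] * Sa[1, 1]))
    rg_se = None
    if cov_theta is not None:
        v11, v12, v22 = Sa[0, 0], Sa[0, 1], Sa[1, 1]
        g = np.zeros(9)
        g[0] = -0.5 * v12 / (v11 ** 1.5 * np.sqrt(v22))
        g[1] = 1.0 / np.sqrt(v11 * v22)
        g[2] = -0.5 * v12 / (np.sqrt(v11) * v22 ** 1.5)
        var_rg = float(g @ cov_theta @ g)
        rg_se = float(np.sqrt(var_rg)) if var_rg > 0 else None
    return GeneticCovarianceEstimate(
        sigma_a=Sa,
        sigma_p=Sp,
        sigma_e=Se,
        genetic_correlation=rg,
        genetic_correlation_se=rg_se,
        n_iterations=n_iter,
        loglik=-0.5 * state["neg2"],
        converged=converged,
        theta_cov=cov_theta,
    )


def ai_reml_from_design(design: Design, K_inv, **kwargs) -> VarianceComponents:
    """Convenience wrapper: run :func:`ai_reml` on a built design."""
    W = design.W if design.has_pe else None
    return ai_reml(design.y, design.X, design.Z, W, K_inv, **kwargs)
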