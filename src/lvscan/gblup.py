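"""Single-trait animal model on latent scores: mixed-model equations,
EM-REML variance components, bivariate genetic correlation, and
back-solving of SNP allele-substitution effects from GEBVs.

The animal model is ``y = X b + W a + e`` with ``Var(a) = H sigma2_a`` and
``Var(e) = I sigma2_e``; ``W`` maps phenotype records to animals carried in
the relationship matrix, so animals without records still receive breeding
values through their relationships.

EM-REML is run on the fixed-effect-projected data rotated into the
eigenbasis of the relationship matrix among recorded animals.  In that
basis the model decomposes into independent scalar (or 2x2, bivariate)
components, which makes each EM iteration O(n) while remaining exactly the
EM algorithm on the REML likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg

from .kinship import RelationshipMatrix

__all__ = [
    "VarianceComponents",
    "GblupSolution",
    "solve_mme",
    "estimate_variance_components",
    "estimate_genetic_correlation",
    "backsolve_snp_effects",
]

log = logging.getLogger(__name__)


@dataclass
class VarianceComponents:
    sigma2_a: float
    sigma2_e: float
    h2_se: float
    converged: bool
    n_iter: int

    @property
    def lam(self) -> float:
        return self.sigma2_e / self.sigma2_a

    @property
    def h2(self) -> float:
        return self.sigma2_a / (self.sigma2_a + self.sigma2_e)


@dataclass
class GblupSolution:
    fixed_solutions: pd.Series
    gebv: pd.Series  # indexed by animal id, all animals in H
    model_tag: str = "trait"
    snp_effects: np.ndarray | None = field(default=None, repr=False)


def _incidence(record_ids, animal_ids) -> np.ndarray:
    pos = {a: i for i, a in enumerate(animal_ids)}
    missing = [a for a in record_ids if a not in pos]
    if missing:
        raise ValueError(f"records for animals not in H: {missing[:5]}")
    W = np.zeros((len(record_ids), len(animal_ids)))
    for r, a in enumerate(record_ids):
        W[r, pos[a]] = 1.0
    return W


def solve_mme(
    y: np.ndarray,
    X: np.ndarray,
    Hinv: RelationshipMatrix,
    lam: float,
    record_ids=None,
    fixed_names=None,
    model_tag: str = "trait",
) -> GblupSolution:
    """Solve Henderson's mixed-model equations for one trait.

    ``record_ids`` gives the animal of each phenotype row (defaults to the
    first ``len(y)`` ids of ``Hinv``).
    """
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != len(y):
        raise ValueError("X rows must match records")
    if lam <= 0:
        raise ValueError("lambda must be positive")
    if record_ids is None:
        record_ids = Hinv.ids[: len(y)]
    W = _incidence(record_ids, Hinv.ids)
    k = X.shape[1]
    rank = np.linalg.matrix_rank(X)
    if rank < k:
        names = fixed_names or [f"x{j}" for j in range(k)]
        # identify offending columns greedily
        keep, bad = [], []
        for j in range(k):
            if np.linalg.matrix_rank(X[:, keep + [j]]) == len(keep) + 1:
                keep.append(j)
            else:
                bad.append(names[j])
        raise ValueError(f"fixed-effect design rank deficient; columns {bad}")
    nH = len(Hinv.ids)
    C = np.zeros((k + nH, k + nH))
    C[:k, :k] = X.T @ X
    C[:k, k:] = X.T @ W
    C[k:, :k] = W.T @ X
    C[k:, k:] = W.T @ W + Hinv.values * lam
    rhs = np.concatenate([X.T @ y, W.T @ y])
    sol = np.linalg.solve(C, rhs)
    names = fixed_names or [f"x{j}" for j in range(k)]
    return GblupSolution(
        fixed_solutions=pd.Series(sol[:k], index=names),
        gebv=pd.Series(sol[k:], index=Hinv.ids),
        model_tag=model_tag,
    )


# --------------------------------------------------------------------------
# REML machinery
# --------------------------------------------------------------------------
def _projected_eigen(
    X: np.ndarray, H: np.ndarray, W: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Eigen-decompose K' (W H W') K where K spans null(X')."""
    K = linalg.null_space(X.T)
    M = W @ H @ W.T
    Mt = K.T @ M @ K
    d, U = np.linalg.eigh(0.5 * (Mt + Mt.T))
    d = np.maximum(d, 1e-10)
    return d, K @ U  # columns: orthonormal basis, KU' y gives rotated data


def estimate_variance_components(
    y: np.ndarray,
    X: np.ndarray,
    Hinv: RelationshipMatrix,
    record_ids=None,
    tol: float = 1e-6,
    max_iter: int = 500,
) -> VarianceComponents:
    """Univariate EM-REML for (sigma2_a, sigma2_e); SE of h2 from the
    information matrix at the optimum (delta method)."""
    y = np.asarray(y, dtype=float)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if len(y) < X.shape[1] + 2:
        raise ValueError("too few records for the fixed effects")
    if record_ids is None:
        record_ids = Hinv.ids[: len(y)]
    W = _incidence(record_ids, Hinv.ids)
    H = np.linalg.inv(Hinv.values)
    d, T = _projected_eigen(X, H, W)
    w = T.T @ y
    m = len(w)

    vy = y.var(ddof=1)
    sa, se = 0.5 * vy, 0.5 * vy
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = d * sa + se
        shrink = d * sa / s
        a_hat = shrink * w
        v_post = d * sa * se / s
        sa_new = float(np.mean((a_hat**2 + v_post) / d))
        se_new = float(np.mean((w - a_hat) ** 2 + v_post))
        rel = max(
            abs(sa_new - sa) / max(sa, 1e-12),
            abs(se_new - se) / max(se, 1e-12),
        )
        sa, se = max(sa_new, 1e-12), max(se_new, 1e-12)
        if rel < tol:
            converged = True
            break
    if not converged:
        log.warning("EM-REML hit iteration cap (%d); returning last iterate",
                    max_iter)

    s = d * sa + se
    info = 0.5 * np.array(
        [
            [np.sum(d**2 / s**2), np.sum(d / s**2)],
            [np.sum(d / s**2), np.sum(1.0 / s**2)],
        ]
    )
    try:
        acov = np.linalg.inv(info)
        tot = sa + se
        grad = np.array([se, -sa]) / tot**2
        h2_var = float(grad @ acov @ grad)
        h2_se = float(np.sqrt(max(h2_var, 0.0)))
    except np.linalg.LinAlgError:
        h2_se = float("nan")
    _ = m
    return VarianceComponents(
        sigma2_a=sa, sigma2_e=se, h2_se=h2_se, converged=converged, n_iter=it
    )


def estimate_genetic_correlation(
    yA: np.ndarray,
    yB: np.ndarray,
    X: np.ndarray,
    Hinv: RelationshipMatrix,
    record_ids=None,
    tol: float = 1e-6,
    max_iter: int = 1000,
) -> dict:
    """Bivariate EM-REML; returns r_g with a standard error.

    Both traits must be recorded on the same animals with the same fixed
    design.  If an EM step leaves the positive-definite cone the offending
    covariance matrix is projected back (eigenvalue clipping) and flagged.
    """
    yA = np.asarray(yA, dtype=float)
    yB = np.asarray(yB, dtype=float)
    if yA.shape != yB.shape:
        raise ValueError("both traits must cover the same records")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if record_ids is None:
        record_ids = Hinv.ids[: len(yA)]
    W = _incidence(record_ids, Hinv.ids)
    H = np.linalg.inv(Hinv.values)
    d, T = _projected_eigen(X, H, W)
    wA, wB = T.T @ yA, T.T @ yB
    Wd = np.column_stack([wA, wB])  # (m, 2)
    m = len(d)

    G0, _ = _project_pd(0.5 * np.cov(Wd, rowvar=False, ddof=1))
    R0 = G0.copy()
    projected = False
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        Ginv = np.linalg.inv(G0)
        Rinv = np.linalg.inv(R0)
        # batched posterior of the per-component 2-vector genetic values
        V = np.linalg.inv(Ginv[None] / d[:, None, None] + Rinv[None])
        mu = np.einsum("ijk,kl,il->ij", V, Rinv, Wd)
        resid = Wd - mu
        G_new = (
            np.einsum("ij,ik,i->jk", mu, mu, 1.0 / d) + (V / d[:, None, None]).sum(0)
        ) / m
        R_new = (np.einsum("ij,ik->jk", resid, resid) + V.sum(0)) / m
        G_new, pg = _project_pd(G_new)
        R_new, pr = _project_pd(R_new)
        projected = projected or pg or pr
        rel = max(
            np.abs(G_new - G0).max() / max(np.abs(G0).max(), 1e-12),
            np.abs(R_new - R0).max() / max(np.abs(R0).max(), 1e-12),
        )
        G0, R0 = G_new, R_new
        if rel < tol:
            converged = True
            break
    if not converged:
        log.warning("bivariate EM-REML hit iteration cap (%d)", max_iter)

    rg = float(G0[0, 1] / np.sqrt(G0[0, 0] * G0[1, 1]))
    rg_se = _rg_se(G0, R0, d, Wd)
    return {
        "r_g": rg,
        "r_g_se": rg_se,
        "G0": G0,
        "R0": R0,
        "converged": converged,
        "projected": projected,
        "n_iter": it,
    }


def _project_pd(M: np.ndarray) -> tuple[np.ndarray, bool]:
    vals, vecs = np.linalg.eigh(0.5 * (M + M.T))
    floor = max(vals.max(), 1e-12) * 1e-6  # relative PD floor
    if vals.min() > floor:
        return M, False
    vals = np.maximum(vals, floor)
    return (vecs * vals) @ vecs.T, True


def _rg_se(G0, R0, d, Wd) -> float:
    """Delta-method SE of r_g from a numerical Hessian of the REML
    log-likelihood in the diagonalised basis."""
    def unpack(p):
        G = np.array([[p[0], p[1]], [p[1], p[2]]])
        R = np.array([[p[3], p[4]], [p[4], p[5]]])
        return G, R

    def negll(p):
        G, R = unpack(p)
        S = G[None] * d[:, None, None] + R[None]
        sign, logdet = np.linalg.slogdet(S)
        if np.any(sign <= 0):
            return np.inf
        quad = np.einsum("ij,ijk,ik->i", Wd, np.linalg.inv(S), Wd)
        return 0.5 * float(np.sum(logdet + quad))

    p0 = np.array([G0[0, 0], G0[0, 1], G0[1, 1], R0[0, 0], R0[0, 1], R0[1, 1]])
    h = np.maximum(np.abs(p0), 1e-3) * 1e-4
    k = len(p0)
    Hm = np.zeros((k, k))
    f0 = negll(p0)
    if not np.isfinite(f0):
        return float("nan")
    for a in range(k):
        for b in range(a, k):
            pa, pb = p0.copy(), p0.copy()
            pa[a] += h[a]
            pa[b] += h[b]
            pb[a] += h[a]
            pb[b] -= h[b]
            pc, pd_ = p0.copy(), p0.copy()
            pc[a] -= h[a]
            pc[b] += h[b]
            pd_[a] -= h[a]
            pd_[b] -= h[b]
            Hm[a, b] = Hm[b, a] = (
                negll(pa) - negll(pb) - negll(pc) + negll(pd_)
            ) / (4 * h[a] * h[b])
    try:
        acov = np.linalg.inv(Hm)
    except np.linalg.LinAlgError:
        return float("nan")
    ga, c, gb = p0[0], p0[1], p0[2]
    rg = c / np.sqrt(ga * gb)
    grad = np.zeros(k)
    grad[0] = -0.5 * rg / ga
    grad[1] = 1.0 / np.sqrt(ga * gb)
    grad[2] = -0.5 * rg / gb
    var = float(grad @ acov @ grad)
    return float(np.sqrt(var)) if var > 0 else float("nan")


# --------------------------------------------------------------------------
# SNP back-solving
# --------------------------------------------------------------------------
def backsolve_snp_effects(
    sol: GblupSolution,
    Zc: np.ndarray,
    G_used: RelationshipMatrix,
    freqs: np.ndarray,
    reconstruction_tol: float = 1e-6,
) -> np.ndarray:
    """u_hat = Zc' G^-1 a_hat / (2 sum p(1-p)) over the genotyped animals.

    With an unblended VanRaden G the reconstruction ``Zc @ u_hat`` equals
    the genotyped GEBVs exactly; with a blended G a warning reports the
    relative reconstruction error.
    """
    a_hat = sol.gebv.reindex(G_used.ids).to_numpy(float)
    if np.isnan(a_hat).any():
        raise ValueError("GEBVs missing for some genotyped animals")
    denom = 2.0 * np.sum(freqs * (1.0 - freqs))
    try:
        Ginv_a = np.linalg.solve(G_used.values, a_hat)
    except np.linalg.LinAlgError as err:
        raise ValueError(
            "G is singular; pass a blended G (alpha < 1) and accept a "
            "reconstruction-tolerance warning"
        ) from err
    u = Zc.T @ Ginv_a / denom
    recon = Zc @ u
    scale = np.linalg.norm(a_hat)
    rel = np.linalg.norm(recon - a_hat) / scale if scale > 0 else 0.0
    if rel > reconstruction_tol:
        log.warning(
            "back-solve reconstruction relative error %.3g (blended or "
            "rank-deficient G)", rel,
        )
    sol.snp_effects = u
    return u
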