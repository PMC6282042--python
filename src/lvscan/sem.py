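"""Latent-variable structural equation model: specification, identification,
maximum-likelihood fitting, fit indices, factor scores and bootstrap checks.

The model follows the classic two-part (measurement + structural) form

    x = Lx xi + delta        y = Ly eta + eps        eta = B eta + G xi + zeta

with diagonal residual matrices, simple-structure loadings (each indicator
loads on exactly one latent) and an acyclic structural part.  Fitting
minimises the ML discrepancy

    F(theta) = ln|Sigma| + tr(S Sigma^-1) - ln|S| - p

with variances log-parameterised so they stay positive; the chi-square
statistic is (n-1) * F(theta_hat).  Robust (sandwich) standard errors and a
scaled-and-shifted adjusted test statistic are available when raw data rows
are supplied.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "SemModel",
    "SemFit",
    "FitIndices",
    "degrees_of_freedom",
    "model_degrees_of_freedom",
    "implied_covariance",
    "fit_ml",
    "independence_fit",
    "fit_indices",
    "factor_scores",
    "bootstrap_model_check",
]

log = logging.getLogger(__name__)

_LOGVAR_FLOOR = np.log(1e-8)


# ==========================================================================
# model specification
# ==========================================================================
@dataclass
class SemModel:
    """Two-latent-block structural model with simple-structure loadings.

    ``scale_setting``:

    * ``"marker"`` — first loading of each latent fixed to 1, latent
      variances free (unstandardised solution; the default).
    * ``"fixed_variance"`` — latent variances fixed to 1, all loadings free.
    * ``"marker_and_variance"`` — both constraints at once (first loadings
      fixed to 1 *and* latent variances fixed to 1); not a standard
      identification but reproduces parameter counts used in some reports.
    """

    latents_x: list[str]  # exogenous latent names
    latents_y: list[str]  # endogenous latent names
    indicators_x: list[str]
    indicators_y: list[str]
    loading_map: dict[str, str]  # indicator -> latent
    gamma_paths: list[tuple[str, str]]  # (endogenous, exogenous)
    b_paths: list[tuple[str, str]] = field(default_factory=list)  # (eta_i, eta_j)
    scale_setting: str = "marker"

    # ------------------------------------------------------------- parsing
    @classmethod
    def from_text(cls, text: str, scale_setting: str = "marker") -> "SemModel":
        """Parse ``latent =~ a + b + c`` / ``latent ~ latent`` lines."""
        loading_map: dict[str, str] = {}
        latent_order: list[str] = []
        regressions: list[tuple[str, str]] = []
        for raw in text.strip().splitlines():
            line = raw.split("#")[0].strip()
            if not line:
                continue
            if "=~" in line:
                lhs, rhs = (s.strip() for s in line.split("=~"))
                if lhs not in latent_order:
                    latent_order.append(lhs)
                for ind in (s.strip() for s in rhs.split("+")):
                    if ind in loading_map:
                        raise ValueError(f"indicator {ind!r} loads twice")
                    loading_map[ind] = lhs
            elif "~" in line:
                lhs, rhs = (s.strip() for s in line.split("~"))
                for src in (s.strip() for s in rhs.split("+")):
                    regressions.append((lhs, src))
            else:
                raise ValueError(f"cannot parse model line: {raw!r}")
        endo = [l for l in latent_order if any(t == l for t, _ in regressions)]
        exo = [l for l in latent_order if l not in endo]
        gamma = [(t, s) for t, s in regressions if s in exo]
        bmat = [(t, s) for t, s in regressions if s in endo]
        ind_x = [i for i, l in loading_map.items() if l in exo]
        ind_y = [i for i, l in loading_map.items() if l in endo]
        model = cls(
            latents_x=exo,
            latents_y=endo,
            indicators_x=ind_x,
            indicators_y=ind_y,
            loading_map=loading_map,
            gamma_paths=gamma,
            b_paths=bmat,
            scale_setting=scale_setting,
        )
        model._check_acyclic()
        return model

    def _check_acyclic(self) -> None:
        # B must be strictly triangular under some ordering of endo latents
        order = {l: k for k, l in enumerate(self.latents_y)}
        adj = {l: [] for l in self.latents_y}
        for tgt, src in self.b_paths:
            adj[src].append(tgt)
        seen: dict[str, int] = {}

        def dfs(u: str) -> None:
            seen[u] = 0
            for v in adj[u]:
                if seen.get(v) == 0:
                    raise ValueError("structural part (B) contains a cycle")
                if v not in seen:
                    dfs(v)
            seen[u] = 1

        for u in self.latents_y:
            if u not in seen:
                dfs(u)
        _ = order  # ordering itself is free

    # ---------------------------------------------------------- bookkeeping
    @property
    def observed(self) -> list[str]:
        return list(self.indicators_x) + list(self.indicators_y)

    @property
    def p(self) -> int:
        return len(self.observed)

    def free_loadings(self) -> list[str]:
        """Indicators whose loading is a free parameter."""
        fix_first = self.scale_setting in ("marker", "marker_and_variance")
        free: list[str] = []
        seen_latent: set[str] = set()
        for ind in self.observed:
            lat = self.loading_map[ind]
            if fix_first and lat not in seen_latent:
                seen_latent.add(lat)
                continue  # marker indicator, loading fixed to 1
            free.append(ind)
        return free

    def latent_variances_free(self) -> bool:
        return self.scale_setting == "marker"

    def parameter_names(self) -> list[str]:
        names = [f"lambda[{i}]" for i in self.free_loadings()]
        names += [f"gamma[{t}~{s}]" for t, s in self.gamma_paths]
        names += [f"beta[{t}~{s}]" for t, s in self.b_paths]
        if self.latent_variances_free():
            names += [f"phi[{l}]" for l in self.latents_x]
            names += [f"psi[{l}]" for l in self.latents_y]
        names += [f"theta[{i}]" for i in self.observed]
        return names

    @property
    def q(self) -> int:
        return len(self.parameter_names())

    def _variance_param_mask(self) -> np.ndarray:
        """Boolean mask of parameters that are variances (log-parameterised)."""
        names = self.parameter_names()
        return np.array(
            [n.startswith(("phi[", "psi[", "theta[")) for n in names]
        )

    # --------------------------------------------------------- matrix build
    def matrices(self, theta: np.ndarray) -> dict[str, np.ndarray]:
        """Assemble Lx, Ly, B, G, Phi, Psi, Theta from the natural-scale
        parameter vector (ordering per :meth:`parameter_names`)."""
        nx, ny = len(self.latents_x), len(self.latents_y)
        px, py = len(self.indicators_x), len(self.indicators_y)
        xi_ix = {l: k for k, l in enumerate(self.latents_x)}
        eta_ix = {l: k for k, l in enumerate(self.latents_y)}
        pos = 0
        free = set(self.free_loadings())
        Lx = np.zeros((px, nx))
        Ly = np.zeros((py, ny))
        lam_entries: list[tuple[str, int, int, str]] = []  # block, i, j, ind
        theta = np.asarray(theta, dtype=float)
        for i, ind in enumerate(self.indicators_x):
            j = xi_ix[self.loading_map[ind]]
            if ind in free:
                lam_entries.append(("x", i, j, ind))
            else:
                Lx[i, j] = 1.0
        for i, ind in enumerate(self.indicators_y):
            j = eta_ix[self.loading_map[ind]]
            if ind in free:
                lam_entries.append(("y", i, j, ind))
            else:
                Ly[i, j] = 1.0
        # fill free loadings in declared order (matches parameter_names)
        for ind in self.free_loadings():
            blk, i, j, _ = next(e for e in lam_entries if e[3] == ind)
            (Lx if blk == "x" else Ly)[i, j] = theta[pos]
            pos += 1
        G = np.zeros((ny, nx))
        for t, s in self.gamma_paths:
            G[eta_ix[t], xi_ix[s]] = theta[pos]
            pos += 1
        B = np.zeros((ny, ny))
        for t, s in self.b_paths:
            B[eta_ix[t], eta_ix[s]] = theta[pos]
            pos += 1
        if self.latent_variances_free():
            Phi = np.diag(theta[pos : pos + nx])
            pos += nx
            Psi = np.diag(theta[pos : pos + ny])
            pos += ny
        else:
            Phi = np.eye(nx)
            Psi = np.eye(ny)
        Theta = np.diag(theta[pos : pos + self.p])
        pos += self.p
        assert pos == len(theta)
        return {"Lx": Lx, "Ly": Ly, "B": B, "G": G, "Phi": Phi,
                "Psi": Psi, "Theta": Theta}


# ==========================================================================
# identification
# ==========================================================================
def degrees_of_freedom(p: int, q: int) -> tuple[int, str]:
    """df = p(p+1)/2 - q with the over/just/under-identified label."""
    df = p * (p + 1) // 2 - q
    label = "overidentified" if df >= 1 else (
        "just-identified" if df == 0 else "underidentified"
    )
    return df, label


def model_degrees_of_freedom(model: SemModel) -> tuple[int, str]:
    return degrees_of_freedom(model.p, model.q)


# ==========================================================================
# implied covariance
# ==========================================================================
def implied_covariance(model: SemModel, theta: np.ndarray) -> np.ndarray:
    """Sigma(theta), observed-variable order = indicators_x + indicators_y."""
    M = model.matrices(theta)
    return _sigma_from_matrices(M, len(model.indicators_x))


def _sigma_from_matrices(M: dict[str, np.ndarray], px: int) -> np.ndarray:
    Lx, Ly, B, G = M["Lx"], M["Ly"], M["B"], M["G"]
    Phi, Psi, Theta = M["Phi"], M["Psi"], M["Theta"]
    ny = B.shape[0]
    ImB = np.eye(ny) - B
    det = np.linalg.det(ImB) if ny else 1.0
    if ny and abs(det) < 1e-12:
        raise np.linalg.LinAlgError("(I - B) is singular")
    A = np.linalg.inv(ImB) if ny else np.zeros((0, 0))
    Ceta = A @ (G @ Phi @ G.T + Psi) @ A.T if ny else np.zeros((0, 0))
    Sxx = Lx @ Phi @ Lx.T
    Syy = Ly @ Ceta @ Ly.T
    Syx = Ly @ A @ G @ Phi @ Lx.T if ny else np.zeros((0, px))
    p = Theta.shape[0]
    Sigma = np.zeros((p, p))
    Sigma[:px, :px] = Sxx
    Sigma[px:, px:] = Syy
    Sigma[px:, :px] = Syx
    Sigma[:px, px:] = Syx.T
    Sigma += Theta
    return 0.5 * (Sigma + Sigma.T)


# ==========================================================================
# ML fitting
# ==========================================================================
@dataclass
class SemFit:
    model: SemModel
    estimates: pd.DataFrame  # name, value, se, robust_se
    S: np.ndarray
    sigma_implied: np.ndarray
    n: int
    fmin: float
    chi2: float
    pvalue: float
    df: int
    converged: bool
    heywood: bool = False
    chi2_scaled_shifted: float | None = None
    pvalue_scaled_shifted: float | None = None
    data_means: np.ndarray | None = None

    @property
    def theta(self) -> np.ndarray:
        return self.estimates["value"].to_numpy()

    def to_table(self) -> pd.DataFrame:
        return self.estimates.copy()

    def report(self) -> str:
        lines = [
            f"SEM fit: n={self.n}, p={self.model.p}, q={self.model.q}, "
            f"df={self.df}",
            f"chi2={self.chi2:.4f} (p={self.pvalue:.4f}), "
            f"converged={self.converged}, heywood={self.heywood}",
        ]
        for row in self.estimates.itertuples(index=False):
            se = f"{row.se:.4f}" if np.isfinite(row.se) else "NA"
            lines.append(f"  {row.name:<22s} {row.value: .4f}  (se {se})")
        return "\n".join(lines)


def _dsigma_list(model: SemModel, theta: np.ndarray) -> list[np.ndarray]:
    """Analytic dSigma/dtheta_k (natural scale) for every free parameter."""
    M = model.matrices(theta)
    Lx, Ly, B, G = M["Lx"], M["Ly"], M["B"], M["G"]
    Phi, Psi = M["Phi"], M["Psi"]
    px, p = len(model.indicators_x), model.p
    nx, ny = len(model.latents_x), len(model.latents_y)
    ImB = np.eye(ny) - B
    A = np.linalg.inv(ImB) if ny else np.zeros((0, 0))
    W = G @ Phi @ G.T + Psi
    Ceta = A @ W @ A.T if ny else np.zeros((0, 0))
    AGP = A @ G @ Phi if ny else np.zeros((0, nx))

    def assemble(dSxx, dSyy, dSyx):
        out = np.zeros((p, p))
        out[:px, :px] = dSxx
        out[px:, px:] = dSyy
        out[px:, :px] = dSyx
        out[:px, px:] = dSyx.T
        return out

    grads: list[np.ndarray] = []
    xi_ix = {l: k for k, l in enumerate(model.latents_x)}
    eta_ix = {l: k for k, l in enumerate(model.latents_y)}
    ix_x = {ind: i for i, ind in enumerate(model.indicators_x)}
    ix_y = {ind: i for i, ind in enumerate(model.indicators_y)}
    for ind in model.free_loadings():
        lat = model.loading_map[ind]
        if ind in ix_x:
            E = np.zeros_like(Lx)
            E[ix_x[ind], xi_ix[lat]] = 1.0
            dSxx = E @ Phi @ Lx.T + Lx @ Phi @ E.T
            dSyx = Ly @ AGP @ E.T if ny else np.zeros((p - px, px))
            grads.append(assemble(dSxx, np.zeros((p - px, p - px)), dSyx))
        else:
            E = np.zeros_like(Ly)
            E[ix_y[ind], eta_ix[lat]] = 1.0
            dSyy = E @ Ceta @ Ly.T + Ly @ Ceta @ E.T
            dSyx = E @ A @ G @ Phi @ Lx.T
            grads.append(assemble(np.zeros((px, px)), dSyy, dSyx))
    for t, s in model.gamma_paths:
        E = np.zeros_like(G)
        E[eta_ix[t], xi_ix[s]] = 1.0
        core = E @ Phi @ G.T + G @ Phi @ E.T
        dSyy = Ly @ A @ core @ A.T @ Ly.T
        dSyx = Ly @ A @ E @ Phi @ Lx.T
        grads.append(assemble(np.zeros((px, px)), dSyy, dSyx))
    for t, s in model.b_paths:
        E = np.zeros_like(B)
        E[eta_ix[t], eta_ix[s]] = 1.0
        dA = A @ E @ A
        dSyy = Ly @ (dA @ W @ A.T + A @ W @ dA.T) @ Ly.T
        dSyx = Ly @ dA @ G @ Phi @ Lx.T
        grads.append(assemble(np.zeros((px, px)), dSyy, dSyx))
    if model.latent_variances_free():
        for l in model.latents_x:
            E = np.zeros((nx, nx))
            E[xi_ix[l], xi_ix[l]] = 1.0
            dSxx = Lx @ E @ Lx.T
            dSyy = Ly @ A @ G @ E @ G.T @ A.T @ Ly.T if ny else np.zeros((0, 0))
            dSyx = Ly @ A @ G @ E @ Lx.T if ny else np.zeros((0, px))
            grads.append(assemble(dSxx, dSyy, dSyx))
        for l in model.latents_y:
            E = np.zeros((ny, ny))
            E[eta_ix[l], eta_ix[l]] = 1.0
            dSyy = Ly @ A @ E @ A.T @ Ly.T
            grads.append(assemble(np.zeros((px, px)), dSyy, np.zeros((p - px, px))))
    for k, ind in enumerate(model.observed):
        D = np.zeros((p, p))
        D[k, k] = 1.0
        grads.append(D)
    return grads


def _pack(model: SemModel, theta_nat: np.ndarray) -> np.ndarray:
    mask = model._variance_param_mask()
    out = theta_nat.copy()
    out[mask] = np.log(np.maximum(theta_nat[mask], 1e-10))
    return out


def _unpack(model: SemModel, x: np.ndarray) -> np.ndarray:
    mask = model._variance_param_mask()
    out = x.copy()
    out[mask] = np.exp(x[mask])
    return out


def _start_values(model: SemModel, S: np.ndarray) -> np.ndarray:
    obs = model.observed
    diag = np.diag(S)
    var_of = dict(zip(obs, diag))
    theta = []
    for ind in model.free_loadings():
        theta.append(1.0)
    theta.extend(0.1 for _ in model.gamma_paths)
    theta.extend(0.1 for _ in model.b_paths)
    if model.latent_variances_free():
        # marker indicator variance as a scale anchor
        seen: set[str] = set()
        marker_var: dict[str, float] = {}
        for ind in obs:
            lat = model.loading_map[ind]
            if lat not in seen:
                seen.add(lat)
                marker_var[lat] = var_of[ind]
        theta.extend(0.5 * marker_var[l] for l in model.latents_x)
        theta.extend(0.5 * marker_var[l] for l in model.latents_y)
    theta.extend(0.5 * var_of[i] for i in obs)
    return np.asarray(theta)


def fit_ml(
    S: np.ndarray,
    n: int,
    model: SemModel,
    data: pd.DataFrame | np.ndarray | None = None,
    max_iter: int = 2000,
    gtol: float = 1e-8,
    n_restarts: int = 3,
) -> SemFit:
    """Fit the model to covariance matrix ``S`` (sample size ``n``) by ML.

    When ``data`` (rows of the observed indicators, model column order) is
    given, sandwich robust standard errors and the scaled-and-shifted
    adjusted test statistic are computed as well.
    """
    S = np.asarray(S, dtype=float)
    p = model.p
    if S.shape != (p, p):
        raise ValueError(f"S must be {p}x{p} for this model")
    eigmin = np.linalg.eigvalsh(S).min()
    if eigmin <= 0:
        raise ValueError(f"S not positive definite (min eigenvalue {eigmin:.3e})")
    df, _ = model_degrees_of_freedom(model)
    if df < 0:
        raise ValueError(f"model underidentified (df={df})")
    sign, logdet_S = np.linalg.slogdet(S)

    mask = model._variance_param_mask()

    def obj_and_grad(x: np.ndarray) -> tuple[float, np.ndarray]:
        theta = _unpack(model, x)
        try:
            Sigma = implied_covariance(model, theta)
            sgn, logdet = np.linalg.slogdet(Sigma)
            if sgn <= 0:
                return 1e10, np.zeros_like(x)
            Sinv = np.linalg.inv(Sigma)
            f = logdet + np.trace(Sinv @ S) - logdet_S - p
            Mgrad = Sinv - Sinv @ S @ Sinv
            dlist = _dsigma_list(model, theta)
            g = np.array([np.sum(Mgrad * dS) for dS in dlist])
            g[mask] *= theta[mask]  # chain rule for log-variances
            return f, g
        except np.linalg.LinAlgError:
            return 1e10, np.zeros_like(x)

    bounds = [
        (_LOGVAR_FLOOR, None) if m else (None, None) for m in mask
    ]
    best = None
    rng = np.random.default_rng(12345)
    for attempt in range(n_restarts):
        theta0 = _start_values(model, S)
        if attempt:
            jitter = rng.normal(0, 0.2, size=len(theta0))
            theta0 = theta0 * np.exp(jitter * mask) + jitter * (~mask) * 0.3
            theta0[mask] = np.maximum(theta0[mask], 1e-4)
        x0 = _pack(model, theta0)
        res = optimize.minimize(
            obj_and_grad, x0, jac=True, method="L-BFGS-B", bounds=bounds,
            options={"maxiter": max_iter, "ftol": 1e-14, "gtol": gtol / 10},
        )
        if best is None or res.fun < best.fun - 1e-12:
            best = res
        if best.fun < 1e-12:
            break
    assert best is not None
    theta_hat = _unpack(model, best.x)
    fval, grad = obj_and_grad(best.x)
    converged = bool(np.linalg.norm(grad, np.inf) < 1e-5 or best.success)
    if not converged:
        log.warning(
            "SEM fit did not converge: |grad|=%.2e after %d evals",
            np.linalg.norm(grad, np.inf), best.nfev,
        )
    heywood = bool(np.any(theta_hat[mask] <= 1.5e-8))

    Sigma_hat = implied_covariance(model, theta_hat)
    chi2 = max((n - 1) * fval, 0.0)
    pvalue = float(stats.chi2.sf(chi2, df)) if df > 0 else 1.0

    se = _naive_se(model, theta_hat, S, n)
    robust_se = np.full_like(se, np.nan)
    chi2_ss = pval_ss = None
    if data is not None:
        Z = _as_matrix(data, model)
        robust_se, chi2_ss, pval_ss = _robust_corrections(
            model, theta_hat, Sigma_hat, Z, chi2, df
        )
    est = pd.DataFrame(
        {
            "name": model.parameter_names(),
            "value": theta_hat,
            "se": se,
            "robust_se": robust_se,
        }
    )
    means = None
    if data is not None:
        means = _as_matrix(data, model).mean(axis=0)
    return SemFit(
        model=model,
        estimates=est,
        S=S,
        sigma_implied=Sigma_hat,
        n=n,
        fmin=fval,
        chi2=chi2,
        pvalue=pvalue,
        df=df,
        converged=converged,
        heywood=heywood,
        chi2_scaled_shifted=chi2_ss,
        pvalue_scaled_shifted=pval_ss,
        data_means=means,
    )


def _as_matrix(data, model: SemModel) -> np.ndarray:
    if isinstance(data, pd.DataFrame):
        return data[model.observed].to_numpy(float)
    return np.asarray(data, dtype=float)


def _naive_se(model: SemModel, theta: np.ndarray, S: np.ndarray, n: int) -> np.ndarray:
    """Normal-theory SEs from the expected information of F_ML."""
    try:
        Sigma = implied_covariance(model, theta)
        Sinv = np.linalg.inv(Sigma)
        dlist = _dsigma_list(model, theta)
        k = len(dlist)
        info = np.zeros((k, k))
        for a in range(k):
            Wa = Sinv @ dlist[a]
            for b in range(a, k):
                info[a, b] = info[b, a] = 0.5 * np.sum(Wa * (dlist[b] @ Sinv).T)
        acov = np.linalg.pinv(info) / (n - 1)
        return np.sqrt(np.maximum(np.diag(acov), 0.0))
    except np.linalg.LinAlgError:
        return np.full(len(theta), np.nan)


def _duplication(p: int) -> np.ndarray:
    """Duplication matrix: vec(A) = D vech(A) for symmetric A."""
    rows = p * p
    cols = p * (p + 1) // 2
    D = np.zeros((rows, cols))
    col = 0
    for j in range(p):
        for i in range(j, p):
            D[i * p + j, col] = 1.0
            D[j * p + i, col] = 1.0
            col += 1
    return D


def _vech(A: np.ndarray) -> np.ndarray:
    p = A.shape[0]
    return np.concatenate([A[j:, j] for j in range(p)])


def _robust_corrections(
    model: SemModel,
    theta: np.ndarray,
    Sigma: np.ndarray,
    Z: np.ndarray,
    chi2: float,
    df: int,
):
    """Sandwich SEs and the scaled-and-shifted adjusted test statistic."""
    n, p = Z.shape
    Zc = Z - Z.mean(axis=0)
    d = np.array([_vech(np.outer(z, z)) for z in Zc])
    Gamma = np.cov(d, rowvar=False, ddof=1)  # asymptotic cov of vech(S)
    Sinv = np.linalg.inv(Sigma)
    D = _duplication(p)
    Wmat = 0.5 * D.T @ np.kron(Sinv, Sinv) @ D
    dlist = _dsigma_list(model, theta)
    Delta = np.column_stack([_vech(dS) for dS in dlist])
    DWD = Delta.T @ Wmat @ Delta
    DWD_inv = np.linalg.pinv(DWD)
    mid = Delta.T @ Wmat @ Gamma @ Wmat @ Delta
    acov = DWD_inv @ mid @ DWD_inv / (n - 1)
    robust_se = np.sqrt(np.maximum(np.diag(acov), 0.0))
    # scaled-and-shifted statistic
    chi2_ss = pval_ss = None
    if df > 0:
        U = Wmat - Wmat @ Delta @ DWD_inv @ Delta.T @ Wmat
        UG = U @ Gamma
        trUG = np.trace(UG)
        trUG2 = np.trace(UG @ UG)
        if trUG2 > 0:
            a = np.sqrt(df / trUG2)
            b = df - a * trUG
            chi2_ss = float(a * chi2 + b)
            pval_ss = float(stats.chi2.sf(max(chi2_ss, 0.0), df))
    return robust_se, chi2_ss, pval_ss


def independence_fit(S: np.ndarray, n: int) -> tuple[float, int]:
    """Chi-square and df of the independence (diagonal Sigma) baseline."""
    S = np.asarray(S, dtype=float)
    p = S.shape[0]
    sign, logdet_S = np.linalg.slogdet(S)
    f = float(np.sum(np.log(np.diag(S))) - logdet_S)
    df = p * (p + 1) // 2 - p
    return max((n - 1) * f, 0.0), df


# ==========================================================================
# fit indices
# ==========================================================================
@dataclass(frozen=True)
class FitIndices:
    gfi: float
    agfi: float
    rmr: float
    cfi: float
    rmsea: float | None


def fit_indices(
    fit: SemFit, baseline_chi2: float | None = None,
    baseline_df: int | None = None,
) -> FitIndices:
    """GFI / AGFI / RMR / CFI / RMSEA for a fitted model.

    The baseline defaults to the independence model on the same S.
    """
    S, Sigma, p = fit.S, fit.sigma_implied, fit.model.p
    n, chi2, df = fit.n, fit.chi2, fit.df
    if baseline_chi2 is None or baseline_df is None:
        baseline_chi2, baseline_df = independence_fit(S, n)
    Sinv_hat = np.linalg.inv(Sigma)
    R = Sinv_hat @ S - np.eye(p)
    gfi = 1.0 - np.trace(R @ R) / np.trace((Sinv_hat @ S) @ (Sinv_hat @ S))
    if df > 0:
        agfi = 1.0 - (p * (p + 1) / (2.0 * df)) * (1.0 - gfi)
    else:
        agfi = np.nan
    resid = S - Sigma
    k = p * (p + 1) / 2.0
    rmr = float(np.sqrt(np.sum(np.tril(resid) ** 2) / k))
    num = max(chi2 - df, 0.0)
    den = max(chi2 - df, baseline_chi2 - baseline_df, 0.0)
    cfi = 1.0 - (num / den if den > 0 else 0.0)
    cfi = min(max(cfi, 0.0), 1.0)
    rmsea = None
    if df > 0:
        rmsea = float(np.sqrt(max(chi2 - df, 0.0) / (df * (n - 1))))
    return FitIndices(gfi=float(gfi), agfi=float(agfi), rmr=rmr,
                      cfi=float(cfi), rmsea=rmsea)


# ==========================================================================
# factor scores
# ==========================================================================
def _latent_obs_cov(model: SemModel, theta: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Cov(latents, observed) and Var(latents); latent order = xi then eta."""
    M = model.matrices(theta)
    Lx, Ly, B, G = M["Lx"], M["Ly"], M["B"], M["G"]
    Phi, Psi = M["Phi"], M["Psi"]
    nx, ny = Phi.shape[0], Psi.shape[0]
    px = Lx.shape[0]
    A = np.linalg.inv(np.eye(ny) - B) if ny else np.zeros((0, 0))
    Ceta = A @ (G @ Phi @ G.T + Psi) @ A.T if ny else np.zeros((0, 0))
    Cxe = Phi @ G.T @ A.T if ny else np.zeros((nx, 0))  # cov(xi, eta)
    nlat = nx + ny
    p = model.p
    C = np.zeros((nlat, p))
    C[:nx, :px] = Phi @ Lx.T
    C[:nx, px:] = Cxe @ Ly.T
    C[nx:, :px] = A @ G @ Phi @ Lx.T if ny else 0.0
    C[nx:, px:] = Ceta @ Ly.T
    V = np.zeros((nlat, nlat))
    V[:nx, :nx] = Phi
    V[:nx, nx:] = Cxe
    V[nx:, :nx] = Cxe.T
    V[nx:, nx:] = Ceta
    return C, V


def factor_scores(
    fit: SemFit,
    data: pd.DataFrame | np.ndarray,
    method: str = "regression",
    standardize: bool = True,
) -> pd.DataFrame:
    """Per-row latent scores (columns: latents_x then latents_y).

    ``regression`` scores are E[latent | observed] under the fitted
    parameters; ``bartlett`` scores are the GLS/ML variant.  Rows with
    missing indicators are dropped (count logged).  With ``standardize``
    scores are rescaled to the latent's model-implied variance.
    """
    if not fit.converged:
        raise ValueError("cannot score from a non-converged fit")
    model = fit.model
    if isinstance(data, pd.DataFrame):
        Z = data[model.observed].to_numpy(float)
        index = data.index
    else:
        Z = np.asarray(data, dtype=float)
        index = pd.RangeIndex(len(Z))
    ok = ~np.isnan(Z).any(axis=1)
    if (~ok).sum():
        log.info("factor_scores: dropping %d rows with missing indicators",
                 int((~ok).sum()))
    Zc = Z[ok] - Z[ok].mean(axis=0)
    theta = fit.theta
    C, V = _latent_obs_cov(model, theta)
    if method == "regression":
        Wt = C @ np.linalg.inv(fit.sigma_implied)
        scores = Zc @ Wt.T
    elif method == "bartlett":
        M = model.matrices(theta)
        Lx, Ly = M["Lx"], M["Ly"]
        nlat = V.shape[0]
        L = np.zeros((model.p, nlat))
        px, nx = Lx.shape
        L[:px, :nx] = Lx
        L[px:, nx:] = Ly
        Th_inv = np.linalg.inv(M["Theta"])
        Wt = np.linalg.pinv(L.T @ Th_inv @ L) @ L.T @ Th_inv
        scores = Zc @ Wt.T
    else:
        raise ValueError(f"unknown scoring method {method!r}")
    if standardize:
        sd_target = np.sqrt(np.diag(V))
        sd_have = scores.std(axis=0, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            factor = np.where(sd_have > 0, sd_target / sd_have, 1.0)
        scores = scores * factor
    names = list(model.latents_x) + list(model.latents_y)
    return pd.DataFrame(scores, columns=names, index=index[ok])


# ==========================================================================
# bootstrap model check
# ==========================================================================
def bootstrap_model_check(
    data: pd.DataFrame | np.ndarray,
    model: SemModel,
    n_draws: int,
    seed: int,
    alpha: float = 0.05,
    transform: str = "bollen-stine",
) -> dict:
    """Resample rows with replacement, refit, and count rejecting draws.

    A draw fails when the model chi-square p-value is below ``alpha`` or the
    refit does not converge.  Returns the failing proportion and counts.

    With the default Bollen-Stine transform the rows are rotated so their
    covariance equals the model-implied covariance of the full-data fit,
    which makes the rejection rate approximately ``alpha`` when the model is
    correct (a naive resample would re-test the sample's own misfit on
    every draw).  ``transform="none"`` gives the naive resample.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    Z = _as_matrix(data, model)
    n = Z.shape[0]
    if transform == "bollen-stine":
        S_full = np.cov(Z, rowvar=False, ddof=1)
        base_fit = fit_ml(S_full, n, model)
        Zc = Z - Z.mean(axis=0)
        S_isqrt = _matrix_power(S_full, -0.5)
        Sig_sqrt = _matrix_power(base_fit.sigma_implied, 0.5)
        Z = Zc @ S_isqrt @ Sig_sqrt
    elif transform != "none":
        raise ValueError(f"unknown transform {transform!r}")
    rng = np.random.default_rng(seed)
    n_fail = n_nonconv = 0
    for _ in range(n_draws):
        rows = rng.integers(0, n, size=n)
        Sb = np.cov(Z[rows], rowvar=False, ddof=1)
        try:
            fit = fit_ml(Sb, n, model, n_restarts=1)
        except (ValueError, np.linalg.LinAlgError):
            n_fail += 1
            n_nonconv += 1
            continue
        if not fit.converged:
            n_nonconv += 1
            n_fail += 1
        elif fit.df > 0 and fit.pvalue < alpha:
            n_fail += 1
    if n_nonconv > n_draws / 2:
        log.warning("bootstrap: %d/%d draws non-convergent", n_nonconv, n_draws)
    return {
        "prop_failing": n_fail / n_draws,
        "n_draws": n_draws,
        "n_nonconvergent": n_nonconv,
    }


def _matrix_power(M: np.ndarray, power: float) -> np.ndarray:
    vals, vecs = np.linalg.eigh(0.5 * (M + M.T))
    if vals.min() <= 0:
        raise np.linalg.LinAlgError("matrix not positive definite")
    return (vecs * vals**power) @ vecs.T
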