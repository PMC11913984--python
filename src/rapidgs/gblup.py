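"""Single- and multi-trait GBLUP with REML variance components.

Single-trait REML profiles the likelihood in the variance ratio
``lambda = sigma_g^2 / sigma_e^2`` on the spectrum of the fixed-effect-
projected relationship matrix; the one-dimensional search has a closed-form
error variance at every ``lambda``, which makes the optimum reproducible to
tight tolerance.  The multi-trait extension runs EM-REML on the same
spectral decomposition, re-used across traits.

Fixed effects are group (population) intercepts.  Candidate prediction uses
the stored weight vector ``alpha`` with ``u_new = K_new,train @ alpha``,
which is algebraically identical to ``sigma_g^2 K_new,train V^-1 (y - X mu)``.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.optimize import minimize_scalar

from .relatedness import GRMatrix

__all__ = ["GblupFit", "fit_gblup", "fit_gblup_multitrait", "predict_unphenotyped",
           "predict_joint_mme"]

LAMBDA_BOUNDS = (1e-6, 1e6)


@dataclass
class GblupFit:
    """Fitted GBLUP model: variance components, group effects, GEBVs."""

    trait_names: tuple[str, ...]
    ids: tuple[str, ...]
    group_levels: tuple[str, ...]
    groups: np.ndarray  # int codes per individual
    mu: np.ndarray  # (n_groups, n_traits) fixed group effects
    g_cov: np.ndarray  # (t, t) genetic covariance
    r_cov: np.ndarray  # (t, t) residual covariance
    gebv: np.ndarray  # (n, t)
    alpha: np.ndarray  # (n, t); u_new = K_new,train @ alpha
    loglik: float
    converged: bool
    n_iter: int
    multitrait: bool
    fallback: bool = False
    y: np.ndarray = field(default=None, repr=False)
    k: np.ndarray = field(default=None, repr=False)

    @property
    def sigma_g(self) -> np.ndarray:
        return np.diag(self.g_cov)

    @property
    def sigma_e(self) -> np.ndarray:
        return np.diag(self.r_cov)

    def heritability(self) -> np.ndarray:
        """Per-trait sigma_g^2 / (sigma_g^2 + sigma_e^2)."""
        return self.sigma_g / (self.sigma_g + self.sigma_e)

    def gebv_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.gebv, index=list(self.ids), columns=list(self.trait_names))

    def to_json(self) -> str:
        """Documented schema: traits, ids, groups, mu, G, R, gebv, loglik."""
        return json.dumps(
            {
                "trait_names": list(self.trait_names),
                "ids": list(self.ids),
                "group_levels": list(self.group_levels),
                "groups": self.groups.tolist(),
                "mu": self.mu.tolist(),
                "g_cov": self.g_cov.tolist(),
                "r_cov": self.r_cov.tolist(),
                "gebv": self.gebv.tolist(),
                "loglik": self.loglik,
                "converged": self.converged,
                "multitrait": self.multitrait,
            }
        )


def _as_k(K) -> tuple[np.ndarray, tuple[str, ...] | None]:
    if isinstance(K, GRMatrix):
        return K.matrix, K.ids
    k = np.asarray(K, dtype=float)
    return k, None


def _design(groups, n) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    if groups is None:
        groups = np.zeros(n, dtype=int)
        return np.ones((n, 1)), groups, ("all",)
    codes, levels = pd.factorize(np.asarray(groups))
    x = np.zeros((n, len(levels)))
    x[np.arange(n), codes] = 1.0
    return x, codes, tuple(str(lev) for lev in levels)


def _check_psd(k: np.ndarray) -> None:
    w = np.linalg.eigvalsh(k)
    if w.min() < -1e-6 * max(1.0, w.max()):
        raise ValueError("relationship matrix is not PSD beyond tolerance")


def fit_gblup(
    y: np.ndarray,
    groups,
    K,
    ids: list[str] | None = None,
    trait_name: str = "trait",
) -> GblupFit:
    """REML GBLUP for one trait with group-intercept fixed effects."""
    y = np.asarray(y, dtype=float).ravel()
    k, k_ids = _as_k(K)
    n = y.shape[0]
    if k.shape != (n, n):
        raise ValueError("K dimension does not match y")
    _check_psd(k)
    x, codes, levels = _design(groups, n)
    p = x.shape[1]

    if np.ptp(y) == 0.0:
        warnings.warn("constant response: sigma_g set to 0", stacklevel=2)
        mu = np.linalg.lstsq(x, y, rcond=None)[0]
        fit_ids = tuple(ids) if ids else (k_ids or tuple(f"ind{i+1}" for i in range(n)))
        return GblupFit(
            trait_names=(trait_name,), ids=fit_ids, group_levels=levels, groups=codes,
            mu=mu[:, None], g_cov=np.zeros((1, 1)), r_cov=np.array([[1e-12]]),
            gebv=np.zeros((n, 1)), alpha=np.zeros((n, 1)), loglik=np.nan,
            converged=True, n_iter=0, multitrait=False, y=y[:, None], k=k,
        )

    # REML projection: orthonormal basis of the complement of col(X)
    l_basis = linalg.null_space(x.T)
    m = l_basis.T @ k @ l_basis
    d, u = np.linalg.eigh(m)
    d = np.clip(d, 0.0, None)
    y_rot = u.T @ (l_basis.T @ y)
    n_eff = y_rot.shape[0]

    def negll(log_lam: float) -> float:
        lam = np.exp(log_lam)
        v = lam * d + 1.0
        s2 = np.mean(y_rot**2 / v)
        return 0.5 * (np.sum(np.log(v)) + n_eff * np.log(s2) + n_eff)

    lo, hi = np.log(LAMBDA_BOUNDS[0]), np.log(LAMBDA_BOUNDS[1])
    res = minimize_scalar(negll, bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-10})
    lam = float(np.exp(res.x))
    # accept a boundary solution if it is at least as good
    for cand in (lo, hi):
        if negll(cand) < res.fun - 1e-12:
            lam = float(np.exp(cand))
    v = lam * d + 1.0
    sigma_e = float(np.mean(y_rot**2 / v))
    sigma_g = lam * sigma_e
    loglik = -negll(np.log(lam)) - 0.5 * n_eff * np.log(2 * np.pi)

    # GLS fixed effects and BLUPs on the full spectrum of K
    df, uf = np.linalg.eigh(k)
    df = np.clip(df, 0.0, None)
    vdiag = sigma_g * df + sigma_e
    xr, yr = uf.T @ x, uf.T @ y
    xtvx = xr.T @ (xr / vdiag[:, None])
    mu = np.linalg.solve(xtvx, xr.T @ (yr / vdiag))
    resid_rot = yr - xr @ mu
    alpha = uf @ (sigma_g * resid_rot / vdiag)
    gebv = k @ alpha

    fit_ids = tuple(ids) if ids else (k_ids or tuple(f"ind{i+1}" for i in range(n)))
    return GblupFit(
        trait_names=(trait_name,),
        ids=fit_ids,
        group_levels=levels,
        groups=codes,
        mu=mu[:, None],
        g_cov=np.array([[sigma_g]]),
        r_cov=np.array([[sigma_e]]),
        gebv=gebv[:, None],
        alpha=alpha[:, None],
        loglik=float(loglik),
        converged=bool(res.success),
        n_iter=int(res.nfev),
        multitrait=False,
        y=y[:, None],
        k=k,
    )


def _psd_floor(a: np.ndarray, floor: float) -> np.ndarray:
    w, v = np.linalg.eigh((a + a.T) / 2.0)
    return (v * np.clip(w, floor, None)) @ v.T


def fit_gblup_multitrait(
    Y: np.ndarray,
    groups,
    K,
    trait_names: list[str] | None = None,
    ids: list[str] | None = None,
    max_iter: int = 20_000,
    tol: float = 1e-8,
) -> GblupFit:
    """EM-REML multi-trait GBLUP sharing one relationship matrix.

    Genetic and residual covariance matrices are estimated on the spectrum
    of the projected K; non-PSD intermediates are projected back to the PSD
    cone (eigenvalue floor).  If EM does not converge in ``max_iter``, the
    fit falls back to independent single-trait fits (logged via warning).
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim != 2 or Y.shape[1] < 2:
        raise ValueError("Y must be (n, t) with at least 2 traits")
    k, k_ids = _as_k(K)
    n, t = Y.shape
    if k.shape != (n, n):
        raise ValueError("K dimension does not match Y")
    _check_psd(k)
    x, codes, levels = _design(groups, n)
    traits = tuple(trait_names) if trait_names else tuple(f"trait{j+1}" for j in range(t))

    l_basis = linalg.null_space(x.T)
    m = l_basis.T @ k @ l_basis
    d, u = np.linalg.eigh(m)
    d = np.clip(d, 0.0, None)
    y_rot = u.T @ (l_basis.T @ Y)  # (n_eff, t)
    n_eff = y_rot.shape[0]

    var0 = np.cov(y_rot.T) if n_eff > 1 else np.eye(t)
    var0 = _psd_floor(np.atleast_2d(var0), 1e-8)
    g_cov = var0 / 2.0
    r_cov = var0 / 2.0
    r_floor = 1e-8 * float(np.trace(var0)) / t

    loglik = -np.inf
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        s = d[:, None, None] * g_cov + r_cov  # (n_eff, t, t)
        s_inv = np.linalg.inv(s)
        ll = -0.5 * float(
            np.sum(np.linalg.slogdet(s)[1])
            + np.einsum("ia,iab,ib->", y_rot, s_inv, y_rot)
        )
        w = np.einsum("ab,ibc,ic->ia", g_cov, s_inv, y_rot)  # G S^-1 y per row
        s_inv_sum = np.einsum("iab->ab", s_inv)
        s_inv_dsum = np.einsum("i,iab->ab", d, s_inv)
        g_sum = (
            np.einsum("i,ia,ib->ab", d, w, w)
            + n_eff * g_cov
            - g_cov @ s_inv_dsum @ g_cov
        )
        e = y_rot - d[:, None] * w
        r_sum = e.T @ e + n_eff * r_cov - r_cov @ s_inv_sum @ r_cov
        g_new = _psd_floor(g_sum / n_eff, 1e-10)
        r_new = _psd_floor(r_sum / n_eff, r_floor)
        if abs(ll - loglik) < tol * (1.0 + abs(ll)):
            g_cov, r_cov, loglik = g_new, r_new, ll
            converged = True
            break
        g_cov, r_cov, loglik = g_new, r_new, ll

    fallback = False
    if not converged:
        warnings.warn(
            f"multi-trait EM-REML did not converge in {max_iter} iterations; "
            "falling back to single-trait fits", stacklevel=2,
        )
        fallback = True
        fits = [fit_gblup(Y[:, j], groups, k, ids=ids, trait_name=traits[j]) for j in range(t)]
        g_cov = np.diag([f.g_cov[0, 0] for f in fits])
        r_cov = np.diag([max(f.r_cov[0, 0], r_floor) for f in fits])

    # GLS fixed effects and BLUPs on the full spectrum of K
    df, uf = np.linalg.eigh(k)
    df = np.clip(df, 0.0, None)
    xr, yr = uf.T @ x, uf.T @ Y
    p = x.shape[1]
    s_inv = np.linalg.inv(df[:, None, None] * g_cov + r_cov)  # (n, t, t)
    a_mat = np.einsum("ia,ib,icd->acbd", xr, xr, s_inv).reshape(p * t, p * t)
    rhs = np.einsum("ia,icd,id->ac", xr, s_inv, yr).reshape(p * t)
    mu = np.linalg.solve(a_mat, rhs).reshape(p, t)
    resid = yr - xr @ mu
    w_rot = np.einsum("ab,ibc,ic->ia", g_cov, s_inv, resid)
    alpha = uf @ w_rot
    gebv = uf @ (df[:, None] * w_rot)

    fit_ids = tuple(ids) if ids else (k_ids or tuple(f"ind{i+1}" for i in range(n)))
    return GblupFit(
        trait_names=traits,
        ids=fit_ids,
        group_levels=levels,
        groups=codes,
        mu=mu,
        g_cov=g_cov,
        r_cov=r_cov,
        gebv=gebv,
        alpha=alpha,
        loglik=float(loglik),
        converged=converged,
        n_iter=it,
        multitrait=True,
        fallback=fallback,
        y=Y,
        k=k,
    )


def predict_unphenotyped(
    fit: GblupFit,
    k_cross: np.ndarray,
    candidate_ids: list[str] | None = None,
) -> pd.DataFrame:
    """GEBVs of unphenotyped candidates from a train x candidate block.

    ``k_cross`` is the (n_train, n_cand) relationship block between the
    fit's training individuals (row order = fit.ids) and the candidates,
    built with the same reference frequencies as the training GRM.
    Candidate ids must not overlap training ids.
    """
    k_cross = np.asarray(k_cross, dtype=float)
    if k_cross.shape[0] != len(fit.ids):
        raise ValueError("cross-GRM row count does not match the training set")
    if candidate_ids is not None:
        overlap = set(candidate_ids) & set(fit.ids)
        if overlap:
            raise ValueError(f"candidate ids overlap training ids: {sorted(overlap)[:5]}")
    u = k_cross.T @ fit.alpha
    idx = candidate_ids if candidate_ids else [f"cand{i+1}" for i in range(k_cross.shape[1])]
    return pd.DataFrame(u, index=idx, columns=list(fit.trait_names))


def predict_joint_mme(fit: GblupFit, k_joint: np.ndarray) -> np.ndarray:
    """Single-trait prediction via Henderson's equations on the joint GRM.

    The first ``len(fit.ids)`` rows/columns of ``k_joint`` must be the
    training individuals; the remainder are unphenotyped candidates whose
    records are missing.  Returns BLUPs for all joint individuals.  This is
    the independent second route for cross-block prediction and must agree
    with :func:`predict_unphenotyped` for invertible joint matrices.
    """
    if fit.multitrait:
        raise ValueError("joint-MME route implemented for single-trait fits")
    n_train = len(fit.ids)
    n_all = k_joint.shape[0]
    sigma_g = float(fit.g_cov[0, 0])
    sigma_e = float(fit.r_cov[0, 0])
    y = fit.y[:, 0]
    x = np.zeros((n_train, len(fit.group_levels)))
    x[np.arange(n_train), fit.groups] = 1.0
    z = np.hstack([np.eye(n_train), np.zeros((n_train, n_all - n_train))])
    # VanRaden matrices over a self-referenced frequency set are singular
    # (the centered scores sum to zero), so a generalized inverse is used;
    # the minimum-norm MME solution still reproduces the candidate BLUPs.
    k_inv = np.linalg.pinv(k_joint, rcond=1e-12, hermitian=True)
    p = x.shape[1]
    lhs = np.zeros((p + n_all, p + n_all))
    lhs[:p, :p] = x.T @ x / sigma_e
    lhs[:p, p:] = x.T @ z / sigma_e
    lhs[p:, :p] = lhs[:p, p:].T
    lhs[p:, p:] = z.T @ z / sigma_e + k_inv / sigma_g
    rhs = np.concatenate([x.T @ y, z.T @ y]) / sigma_e
    sol = np.linalg.lstsq(lhs, rhs, rcond=None)[0]
    return sol[p:]
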