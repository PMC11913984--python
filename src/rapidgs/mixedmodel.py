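"""Average-information REML for Gaussian mixed models with independent
random terms and term-specific variances.

The model is ``y = X beta + sum_k Z_k u_k + e`` with ``u_k ~ N(0, s2_k I)``
and ``e ~ N(0, s2_e I)``.  Heterogeneous variance groups (e.g. a separate
genetic variance per population) are expressed by passing one term per
group.  V-inverse products use the Woodbury identity through the dense
Cholesky of ``C = G^-1 + Z'Z / s2_e``, which keeps each iteration at one
q x q factorization plus sparse trace assembly.

Safeguards: step halving on likelihood decrease, variance floor for
components driven negative (estimates pinned at the floor report ~0).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import linalg, sparse

__all__ = ["RandomTerm", "MixedModelFit", "reml"]


@dataclass
class RandomTerm:
    """One independent random factor: name, incidence matrix, level labels."""

    name: str
    z: sparse.csc_matrix
    levels: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        self.z = sparse.csc_matrix(self.z)

    @property
    def n_levels(self) -> int:
        return self.z.shape[1]


@dataclass
class MixedModelFit:
    term_names: tuple[str, ...]
    theta: np.ndarray  # variance per random term
    sigma2_e: float
    beta: np.ndarray
    beta_cov: np.ndarray
    blups: dict[str, np.ndarray]
    loglik: float
    converged: bool
    n_iter: int
    pinned: tuple[str, ...] = ()  # components held at the variance floor

    def variance(self, name: str) -> float:
        return float(self.theta[self.term_names.index(name)])


def _spd_solve(c: np.ndarray):
    try:
        return linalg.cho_factor(c, lower=True, check_finite=False)
    except linalg.LinAlgError:
        # jitter once; the engine floors variances so this is rare
        return linalg.cho_factor(
            c + 1e-8 * np.eye(c.shape[0]) * np.trace(c) / c.shape[0],
            lower=True,
            check_finite=False,
        )


def reml(
    y: np.ndarray,
    x: np.ndarray,
    terms: list[RandomTerm],
    max_iter: int = 100,
    tol: float = 1e-6,
    theta0: np.ndarray | None = None,
    sigma2_e0: float | None = None,
) -> MixedModelFit:
    """Fit variance components by AI-REML (Newton on the average information).

    Returns REML estimates, GLS fixed effects with their covariance, and
    BLUPs per term at the final estimates.
    """
    y = np.asarray(y, dtype=float).ravel()
    x = np.atleast_2d(np.asarray(x, dtype=float))
    n = y.shape[0]
    if x.shape[0] != n:
        raise ValueError("X row count does not match y")
    if np.linalg.matrix_rank(x) < x.shape[1]:
        raise ValueError("fixed-effect design is rank deficient")
    n_terms = len(terms)
    if n_terms == 0:
        raise ValueError("at least one random term is required")

    z = sparse.hstack([t.z for t in terms], format="csc")
    q_sizes = [t.n_levels for t in terms]
    q_off = np.concatenate([[0], np.cumsum(q_sizes)])
    q = int(q_off[-1])
    ztz = (z.T @ z).tocsc()
    zty = z.T @ y
    ztx = z.T @ x
    ztz_diag_blocks = [
        float(terms[k].z.multiply(terms[k].z).sum()) for k in range(n_terms)
    ]  # tr(Z_k' Z_k)

    var_y = float(np.var(y))
    if var_y == 0:
        var_y = 1.0
    floor = 1e-8 * var_y
    theta = (
        np.asarray(theta0, dtype=float)
        if theta0 is not None
        else np.full(n_terms, var_y / (n_terms + 1))
    )
    s2e = float(sigma2_e0) if sigma2_e0 is not None else var_y / (n_terms + 1)
    theta = np.clip(theta, floor, None)
    s2e = max(s2e, floor)

    state: dict = {}

    def evaluate(theta_v: np.ndarray, s2e_v: float) -> float:
        """Compute loglik and cache the pieces needed for scores/AI."""
        g = np.concatenate(
            [np.full(q_sizes[k], theta_v[k]) for k in range(n_terms)]
        )
        c = ztz.toarray() / s2e_v
        c[np.arange(q), np.arange(q)] += 1.0 / g
        cho = _spd_solve(c)
        logdet_c = 2.0 * float(np.sum(np.log(np.diag(cho[0]))))

        def vinv(a):
            dense = a.toarray() if sparse.issparse(a) else np.asarray(a, dtype=float)
            zta = z.T @ dense
            return dense / s2e_v - (z @ linalg.cho_solve(cho, zta, check_finite=False)) / s2e_v**2

        viy = vinv(y)
        vix = vinv(x)
        xtvix = x.T @ vix
        xtviy = x.T @ viy
        cf = linalg.cho_factor(xtvix, check_finite=False)
        beta = linalg.cho_solve(cf, xtviy, check_finite=False)
        py = viy - vix @ beta
        logdet_v = (
            n * np.log(s2e_v)
            + float(np.sum(np.array(q_sizes) * np.log(theta_v)))
            + logdet_c
        )
        ll = -0.5 * (logdet_v + np.linalg.slogdet(xtvix)[1] + float(y @ py))
        state.update(
            cho=cho, beta=beta, py=py, vix=vix, xtvix=xtvix, xtvix_cf=cf, g=g,
            theta=theta_v.copy(), s2e=s2e_v, vinv=vinv,
        )
        return float(ll)

    ll = evaluate(theta, s2e)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        cho = state["cho"]
        py = state["py"]
        vix = state["vix"]
        cf = state["xtvix_cf"]

        cinv = linalg.cho_solve(cho, np.eye(q), check_finite=False)

        # scores
        zt_py = z.T @ py
        scores = np.empty(n_terms + 1)
        f_list = []
        for k in range(n_terms):
            sl = slice(q_off[k], q_off[k + 1])
            s_k = ztz[:, sl]  # q x q_k sparse
            cinv_sk = (s_k.T @ cinv).T
            tr_vinv = ztz_diag_blocks[k] / s2e - float(
                s_k.multiply(cinv_sk).sum()
            ) / s2e**2
            b_k = vix.T @ terms[k].z  # p x q_k
            tr_p = tr_vinv - float(np.sum(b_k * linalg.cho_solve(cf, b_k, check_finite=False)))
            quad = float(zt_py[sl] @ zt_py[sl])
            scores[k] = -0.5 * (tr_p - quad)
            f_list.append(terms[k].z @ zt_py[sl])
        tr_vinv_e = n / s2e - float(ztz.multiply(cinv).sum()) / s2e**2
        x_vi2x = vix.T @ vix
        tr_p_e = tr_vinv_e - float(np.trace(linalg.cho_solve(cf, x_vi2x, check_finite=False)))
        scores[n_terms] = -0.5 * (tr_p_e - float(py @ py))
        f_list.append(py)

        # average information on P-projected working variates
        f_mat = np.column_stack(f_list)
        vif = state["vinv"](f_mat)
        pf = vif - vix @ linalg.cho_solve(cf, vix.T @ f_mat, check_finite=False)
        ai = 0.5 * (f_mat.T @ pf)
        ai = (ai + ai.T) / 2.0

        params = np.concatenate([state["theta"], [state["s2e"]]])
        pinned_mask = (params <= floor * 1.001) & (scores < 0)
        free = ~pinned_mask
        step = np.zeros_like(params)
        try:
            step[free] = np.linalg.solve(
                ai[np.ix_(free, free)] + 1e-12 * np.eye(int(free.sum())),
                scores[free],
            )
        except np.linalg.LinAlgError:
            step[free] = scores[free] * params[free] ** 2 / var_y  # crude EM-ish

        improved = False
        for _ in range(12):
            proposal = np.clip(params + step, floor, None)
            ll_new = evaluate(proposal[:-1], float(proposal[-1]))
            if np.isfinite(ll_new) and ll_new >= ll - 1e-10:
                improved = True
                break
            step *= 0.5
        if not improved:
            # restore the best state and stop
            ll_new = evaluate(params[:-1], float(params[-1]))
            converged = True
            theta, s2e = params[:-1], float(params[-1])
            ll = ll_new
            break

        delta = np.max(np.abs(proposal - params) / (params + floor))
        theta, s2e = proposal[:-1], float(proposal[-1])
        dll = ll_new - ll
        ll = ll_new
        if delta < tol or abs(dll) < 1e-8 * (1.0 + abs(ll)):
            converged = True
            break

    # BLUPs at the final estimates
    py = state["py"]
    blups = {}
    for k, term in enumerate(terms):
        sl = slice(q_off[k], q_off[k + 1])
        blups[term.name] = theta[k] * np.asarray(term.z.T @ py).ravel()
    beta_cov = np.linalg.inv(state["xtvix"])
    pinned = tuple(
        terms[k].name for k in range(n_terms) if theta[k] <= floor * 1.001
    )
    return MixedModelFit(
        term_names=tuple(t.name for t in terms),
        theta=theta,
        sigma2_e=s2e,
        beta=state["beta"],
        beta_cov=beta_cov,
        blups=blups,
        loglik=ll,
        converged=converged,
        n_iter=it,
        pinned=pinned,
    )
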