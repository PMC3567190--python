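"""Independent reference implementations used to validate the package.

These deliberately avoid the eigendecomposition shortcut and the analytic
integration path: the dense oracle works with explicit inverses and
determinants of the full covariance, and the numeric oracle integrates the
effects out by quadrature.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.integrate import simpson
from scipy.optimize import minimize


def dense_log_marginal(
    y: np.ndarray,
    X_gamma: np.ndarray,
    K: np.ndarray,
    sigma_a2: float,
    sigma_b2: float,
) -> float:
    """Marginal log-likelihood via explicit dense H = sigma_b2 K + I.

    Same additive-constant convention as the package: all constants kept.
    """
    n = y.size
    q = X_gamma.shape[1]
    H = sigma_b2 * K + np.eye(n)
    Hi = np.linalg.inv(H)
    sign, logdet_h = np.linalg.slogdet(H)
    assert sign > 0
    W = np.column_stack([np.ones(n), X_gamma])
    A = W.T @ Hi @ W
    if q:
        A[1:, 1:] += np.eye(q) / sigma_a2
    sign, logdet_a = np.linalg.slogdet(A)
    assert sign > 0
    bvec = W.T @ Hi @ y
    S = float(y @ Hi @ y - bvec @ np.linalg.solve(A, bvec))
    return (
        -0.5 * logdet_h
        - 0.5 * logdet_a
        - (0.5 * q * math.log(sigma_a2) if q else 0.0)
        - 0.5 * (n - 1) * math.log(S / 2.0)
        - 0.5 * (n - 1) * math.log(2.0 * math.pi)
        + math.lgamma(0.5 * (n - 1))
    )


def _fd_hessian(f, x0: np.ndarray, eps: float = 1e-4) -> np.ndarray:
    d = x0.size
    H = np.empty((d, d))
    for i in range(d):
        for j in range(i, d):
            pp = x0.copy(); pp[i] += eps; pp[j] += eps
            pm = x0.copy(); pm[i] += eps; pm[j] -= eps
            mp = x0.copy(); mp[i] -= eps; mp[j] += eps
            mm = x0.copy(); mm[i] -= eps; mm[j] -= eps
            H[i, j] = H[j, i] = (f(pp) - f(pm) - f(mp) + f(mm)) / (4 * eps * eps)
    return H


def numeric_log_marginal(
    y: np.ndarray,
    X_gamma: np.ndarray,
    K: np.ndarray,
    sigma_a2: float,
    sigma_b2: float,
    n_tau: int = 601,
    gh_nodes: int = 24,
    tau_half_width: float = 12.0,
) -> float:
    """Brute-force integration over (beta, mu, log tau).

    The inner (mu, beta) integral at each tau uses tensor Gauss-Hermite
    quadrature centered at the numerically located mode of the integrand
    with a finite-difference Hessian; the outer integral over log tau uses
    Simpson's rule on a wide grid.  No analytic integration identities are
    used anywhere.
    """
    n = y.size
    q = X_gamma.shape[1]
    d = q + 1
    H = sigma_b2 * K + np.eye(n)
    Hi = np.linalg.inv(H)
    sign, logdet_h = np.linalg.slogdet(H)
    assert sign > 0
    W = np.column_stack([np.ones(n), X_gamma])

    def f(theta: np.ndarray) -> float:
        # tau-scaled negative exponent of likelihood x beta-prior
        r = y - W @ theta
        val = 0.5 * float(r @ Hi @ r)
        if q:
            val += 0.5 * float(theta[1:] @ theta[1:]) / sigma_a2
        return val

    res = minimize(f, np.zeros(d), method="BFGS",
                   options={"gtol": 1e-12, "maxiter": 2000})
    theta_star = res.x
    f_star = float(res.fun)
    Hf = _fd_hessian(f, theta_star)
    Lh = np.linalg.cholesky(Hf)
    logdet_lh = float(np.sum(np.log(np.diag(Lh))))

    nodes, weights = np.polynomial.hermite.hermgauss(gh_nodes)
    grids = np.meshgrid(*([nodes] * d), indexing="ij")
    XI = np.stack([gg.ravel() for gg in grids], axis=1)       # (m, d)
    logw = np.log(weights)
    wgrids = np.meshgrid(*([logw] * d), indexing="ij")
    LOGW = sum(gg.ravel() for gg in wgrids)                   # (m,)
    # theta(xi, tau) = theta* + sqrt(2/tau) Lh^{-T} xi
    DIR = np.linalg.solve(Lh.T, XI.T).T                        # (m, d)

    t_center = math.log((n - 1) / (2.0 * f_star))
    tgrid = np.linspace(t_center - tau_half_width,
                        t_center + tau_half_width, n_tau)

    # vectorized f over many theta rows
    def f_rows(TH: np.ndarray) -> np.ndarray:
        R = y[None, :] - TH @ W.T
        vals = 0.5 * np.einsum("ij,jk,ik->i", R, Hi, R)
        if q:
            B = TH[:, 1:]
            vals = vals + 0.5 * np.einsum("ij,ij->i", B, B) / sigma_a2
        return vals

    log_j = np.empty(n_tau)
    xi_sq = np.einsum("ij,ij->i", XI, XI)
    for it, t in enumerate(tgrid):
        tau = math.exp(t)
        TH = theta_star[None, :] + math.sqrt(2.0 / tau) * DIR
        fv = f_rows(TH)
        # sum_i w_i exp(-tau f_i + |xi_i|^2), in log space
        terms = LOGW - tau * fv + xi_sq
        mx = terms.max()
        log_inner = mx + math.log(np.exp(terms - mx).sum())
        log_inner += 0.5 * d * math.log(2.0 / tau) - logdet_lh
        log_j[it] = (
            0.5 * (n + q) * t
            - 0.5 * n * math.log(2.0 * math.pi)
            - 0.5 * logdet_h
            - (0.5 * q * math.log(2.0 * math.pi * sigma_a2) if q else 0.0)
            + log_inner
        )
    mx = log_j.max()
    return mx + math.log(simpson(np.exp(log_j - mx), x=tgrid))
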