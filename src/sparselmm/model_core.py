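"""Model parameters, hyper-parameter re-parameterization and variance summaries.

The model is

    y = 1 mu + X beta + u + e,      u ~ N(0, sigma_b^2/tau K),
    e ~ N(0, I/tau),                beta_j ~ pi N(0, sigma_a^2/tau) + (1-pi) d0,

with improper flat/scale priors on (mu, tau).  Instead of priors on the raw
variance scales, the model is parameterized by interpretable quantities:

* ``h``   — approximately the expected proportion of phenotypic variance
  explained by all genetic terms together,
* ``rho`` — approximately the expected share of that genetic variance coming
  from the sparse (large) effects; ``rho = 0`` is a pure linear mixed model,
  ``rho = 1`` pure variable-selection regression,
* ``pi``  — prior inclusion proportion, uniform on the log scale over
  ``[1/p, 1]``.

The bridge is

    h   = (p pi s_a sigma_a^2 + s_b sigma_b^2) / (1 + p pi s_a sigma_a^2 + s_b sigma_b^2)
    rho =  p pi s_a sigma_a^2 / (p pi s_a sigma_a^2 + s_b sigma_b^2)

where ``s_a`` is the average per-marker genotype variance and ``s_b`` the mean
diagonal of the relatedness matrix.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "HyperState",
    "EffectState",
    "VarianceReport",
    "sample_variance",
    "compute_pve_pge",
    "hyper_to_variances",
    "variances_to_hyper",
    "log_prior_hyper",
]


def sample_variance(x: np.ndarray) -> float:
    """Population-style variance ``V(x) = (1/n) sum (x_i - xbar)^2``."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("sample_variance of an empty vector")
    return float(np.mean((x - np.mean(x)) ** 2))


def hyper_to_variances(
    h: float, rho: float, pi: float, p: int, s_a: float, s_b: float
) -> tuple[float, float]:
    """Map ``(h, rho, pi)`` to the relative variance scales.

    With ``G = h/(1-h)``:

        sigma_a^2 = rho G / (p pi s_a)
        sigma_b^2 = (1 - rho) G / s_b

    Forward-mapping back through :func:`variances_to_hyper` is the identity
    on the interior of the domain.
    """
    if not (0.0 <= h < 1.0):
        raise ValueError(f"h must be in [0, 1), got {h}")
    if not (0.0 <= rho <= 1.0):
        raise ValueError(f"rho must be in [0, 1], got {rho}")
    if not (0.0 < pi <= 1.0):
        raise ValueError(f"pi must be in (0, 1], got {pi}")
    G = h / (1.0 - h)
    if rho > 0.0:
        if s_a <= 0.0:
            raise ValueError("s_a must be positive when rho > 0")
        sigma_a2 = rho * G / (p * pi * s_a)
    else:
        sigma_a2 = 0.0
    if rho < 1.0:
        if s_b <= 0.0:
            raise ValueError("s_b must be positive when rho < 1")
        sigma_b2 = (1.0 - rho) * G / s_b
    else:
        sigma_b2 = 0.0
    return sigma_a2, sigma_b2


def variances_to_hyper(
    sigma_a2: float, sigma_b2: float, pi: float, p: int, s_a: float, s_b: float
) -> tuple[float, float]:
    """Inverse of :func:`hyper_to_variances`: recover ``(h, rho)``."""
    va = p * pi * s_a * sigma_a2
    vb = s_b * sigma_b2
    tot = va + vb
    h = tot / (1.0 + tot)
    rho = va / tot if tot > 0 else 0.0
    return h, rho


@dataclass
class HyperState:
    """Hyper-parameter coordinates ``(h, rho, log pi)`` with derived scales.

    The derived pair ``(sigma_a2, sigma_b2)`` is kept consistent with
    ``(h, rho, pi)`` through :func:`hyper_to_variances` at construction.
    """

    h: float
    rho: float
    log_pi: float
    sigma_a2: float
    sigma_b2: float

    @classmethod
    def from_h_rho_logpi(
        cls, h: float, rho: float, log_pi: float, p: int, s_a: float, s_b: float
    ) -> "HyperState":
        sa2, sb2 = hyper_to_variances(h, rho, math.exp(log_pi), p, s_a, s_b)
        return cls(h=h, rho=rho, log_pi=log_pi, sigma_a2=sa2, sigma_b2=sb2)

    @property
    def pi(self) -> float:
        return math.exp(self.log_pi)


@dataclass
class EffectState:
    """One posterior draw of the model effects given ``(gamma, hyper)``."""

    gamma: np.ndarray        # included marker indices, ordered
    beta_gamma: np.ndarray   # length |gamma|
    u: np.ndarray            # random effects, original basis, length n
    mu: float
    tau: float

    def beta_full(self, p: int) -> np.ndarray:
        b = np.zeros(p)
        b[self.gamma] = self.beta_gamma
        return b


@dataclass
class VarianceReport:
    pve: float
    pge: float


def compute_pve_pge(g_sparse: np.ndarray, u: np.ndarray, tau: float) -> VarianceReport:
    """PVE and PGE of one effect draw.

        pve = V(g + u) / (V(g + u) + 1/tau)
        pge = V(g) / V(g + u)          (0 by convention when V(g + u) = 0)

    with ``g = X beta`` the sparse genetic component and ``V`` the
    population-style variance :func:`sample_variance`.
    """
    if tau <= 0:
        raise ValueError(f"tau must be positive, got {tau}")
    g_sparse = np.asarray(g_sparse, dtype=float)
    u = np.asarray(u, dtype=float)
    v_tot = sample_variance(g_sparse + u)
    if v_tot == 0.0:
        return VarianceReport(pve=0.0, pge=0.0)
    pve = v_tot / (v_tot + 1.0 / tau)
    pge = sample_variance(g_sparse) / v_tot
    return VarianceReport(pve=float(pve), pge=float(min(pge, 1.0)))


def log_prior_hyper(state: HyperState, p: int) -> float:
    """Log prior density of ``(h, rho, log pi)``.

    Independent uniforms: ``h`` on (0, 1), ``rho`` on (0, 1) and ``log pi``
    on ``[log(1/p), 0]``.  Returns ``-inf`` outside the support.
    """
    if not (0.0 < state.h < 1.0):
        return -math.inf
    if not (0.0 <= state.rho <= 1.0):
        return -math.inf
    lo = -math.log(p)
    if not (lo <= state.log_pi <= 0.0):
        return -math.inf
    # densities: 1 * 1 * 1/log(p)
    return -math.log(math.log(p)) if p > 1 else 0.0
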