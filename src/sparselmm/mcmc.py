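"""Metropolis-Hastings sampler over (gamma, h, rho, log pi).

The indicator set gamma uses a rank-based proposal: markers are ordered by
their marginal association with the phenotype and add-moves favour
top-ranked markers through a geometric decay (mixed with a uniform floor so
every marker keeps positive proposal mass).  Hyper-parameters move by
symmetric random walks with reflection at their support boundaries.

Likelihood bookkeeping: the sampler maintains the weighted Gram matrix
``M = W^T D W`` of the current design ``W = [1, X_gamma]`` (in the kinship
eigenbasis, ``D = diag(1/(sigma_b^2 delta_i + 1))``).  Adding/removing a
marker updates one row/column in O(n q); only an accepted change of
``sigma_b^2`` forces a full O(n q^2) rebuild.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.linalg.blas import dsyrk as _dsyrk
from scipy.linalg.lapack import dpotrf as _dpotrf
from scipy.linalg.lapack import dtrtrs as _dtrtrs

from .eigen_likelihood import (
    TransformedData,
    reml_lmm,
    transform_data,
    variance_in_transformed_basis,
)
from .geno_io import GenotypeMatrix, Kinship, PhenotypeVector
from .model_core import HyperState

__all__ = [
    "ProposalConfig",
    "ChainConfig",
    "MarkerRanking",
    "PosteriorSamples",
    "rank_markers",
    "propose_gamma",
    "propose_hyper",
    "Sampler",
    "run_mcmc",
    "save_hyp",
    "save_param",
]

MODES = ("bslmm", "bvsr", "lmm_bayes", "bslmm_eb")


@dataclass
class ProposalConfig:
    """Tuning knobs for the MH proposal kernel.

    The defaults were tuned on simulated data for 20-40% acceptance; the
    published description of the rank-based kernel leaves these details
    open, so everything is exposed here.
    """

    geometric_rank_param: float = 0.3
    p_add: float = 0.4
    p_remove: float = 0.4
    p_swap: float = 0.2
    uniform_add_prob: float = 0.2   # uniform floor mixed into add-moves
    hyper_step_h: float = 0.02
    hyper_step_rho: float = 0.02
    hyper_step_logpi: Optional[float] = None  # default 0.1 * log(p)
    long_range_prob: float = 0.05
    compound_max: int = 5
    hyper_move_prob: float = 0.25
    q_cap: Optional[int] = None     # default min(n - 2, 300)

    def __post_init__(self) -> None:
        tot = self.p_add + self.p_remove + self.p_swap
        if not math.isclose(tot, 1.0, abs_tol=1e-9):
            raise ValueError("p_add + p_remove + p_swap must sum to 1")
        if not (0.0 < self.geometric_rank_param < 1.0):
            raise ValueError("geometric_rank_param must be in (0, 1)")


@dataclass
class ChainConfig:
    n_iter: int = 110_000        # total iterations, burn-in included
    burn_in: int = 10_000
    thin: int = 10
    seed: int = 0
    record_effects: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.burn_in < self.n_iter):
            raise ValueError("need 0 <= burn_in < n_iter")
        if self.thin < 1:
            raise ValueError("thin must be >= 1")


class MarkerRanking:
    """Marker order by marginal association plus geometric proposal weights."""

    def __init__(self, order: np.ndarray, geometric_param: float,
                 uniform_mix: float) -> None:
        self.order = np.asarray(order, dtype=int)
        p = self.order.size
        self.p = p
        self.rank_of = np.empty(p, dtype=int)
        self.rank_of[self.order] = np.arange(p)
        g = geometric_param
        with np.errstate(under="ignore"):
            self.w = g ** self.rank_of.astype(float)
        self.z_all = float(np.sum(self.w))
        self.w_cumsum = np.cumsum(self.w[self.order])  # by rank
        self.uniform_mix = uniform_mix


def rank_markers(
    td: Optional[TransformedData],
    g: GenotypeMatrix,
    y: PhenotypeVector | np.ndarray,
) -> np.ndarray:
    """Markers sorted by decreasing squared marginal correlation with y.

    Zero-variance markers score 0; ties break by marker index.  The
    ``td`` argument is accepted for interface symmetry but unused (ranking
    happens in the original basis).
    """
    yv = y.values if isinstance(y, PhenotypeVector) else np.asarray(y, float)
    X = g.dosages
    yc = yv - yv.mean()
    yy = float(yc @ yc)
    # x_c . y_c == x . y_c because y_c sums to zero
    num = (X.T @ yc) ** 2
    col_mean = X.mean(axis=0)
    col_ss = np.einsum("ij,ij->j", X, X) - X.shape[0] * col_mean ** 2
    ok = (col_ss > 1e-12) & (yy > 0)
    score = np.where(ok, num / np.where(ok, col_ss, 1.0) / max(yy, 1e-300), 0.0)
    return np.lexsort((np.arange(g.p), -score))


# ---------------------------------------------------------------------------
# gamma proposal
# ---------------------------------------------------------------------------

def _eff_move_probs(q: int, p: int, q_cap: int, cfg: ProposalConfig
                    ) -> tuple[float, float, float]:
    """Renormalized (add, remove, swap) probabilities given the state."""
    can_add = q < p and q < q_cap
    can_remove = q >= 1
    can_swap = q >= 1 and q < p
    pa = cfg.p_add if can_add else 0.0
    pr = cfg.p_remove if can_remove else 0.0
    ps = cfg.p_swap if can_swap else 0.0
    tot = pa + pr + ps
    if tot == 0.0:
        raise ValueError("no gamma move available from this state")
    return pa / tot, pr / tot, ps / tot


def _add_log_density(wj: float, w_ex: float, n_ex: int, u: float) -> float:
    if w_ex <= 0.0:
        return -math.log(n_ex)
    return math.log((1.0 - u) * wj / w_ex + u / n_ex)


def _sample_excluded(
    mask: np.ndarray, ranking: MarkerRanking, w_ex: float,
    rng: np.random.Generator,
) -> int:
    """Draw an excluded marker from the geometric/uniform mixture.

    Rejection sampling against the full-marker distributions is tried
    first (cheap when few markers are included); it falls back to explicit
    masked sampling when the included set holds most of the proposal mass.
    """
    p = ranking.p
    u = ranking.uniform_mix
    if w_ex > 0.0 and rng.random() >= u:
        # rejection against the all-marker geometric pays off when the
        # included set holds little of the proposal mass
        if w_ex > 0.5 * ranking.z_all:
            c = ranking.w_cumsum
            for _ in range(8):
                i = int(c.searchsorted(rng.random() * c[-1], side="right"))
                k = int(ranking.order[min(i, p - 1)])
                if not mask[k]:
                    return k
        else:
            # mass concentrates on the first few excluded ranks: scan a
            # rank-ordered prefix, vectorized
            target = rng.random() * w_ex
            limit = min(p, 4 * int(mask.sum()) + 200)
            head = ranking.order[:limit]
            wts = np.where(mask[head], 0.0, ranking.w[head])
            cs = np.cumsum(wts)
            if cs[-1] >= target:
                i = int(cs.searchsorted(target, side="left"))
                return int(head[min(i, limit - 1)])
        excl = np.flatnonzero(~mask)
        cw = np.cumsum(ranking.w[excl])
        if cw[-1] > 0.0:
            i = int(cw.searchsorted(rng.random() * cw[-1], side="right"))
            return int(excl[min(i, excl.size - 1)])
        return int(excl[rng.integers(excl.size)])
    for _ in range(30):
        k = int(rng.integers(p))
        if not mask[k]:
            return k
    excl = np.flatnonzero(~mask)
    return int(excl[rng.integers(excl.size)])


def propose_gamma(
    current: Sequence[int],
    ranking: MarkerRanking,
    cfg: ProposalConfig,
    rng: np.random.Generator,
    q_cap: Optional[int] = None,
    mask: Optional[np.ndarray] = None,
    w_in: Optional[float] = None,
) -> tuple[set[int], float]:
    """One add/remove/swap proposal.

    Returns the proposed set and ``log q(gamma | gamma') - log q(gamma' |
    gamma)``, the Hastings correction making the kernel exact.  ``mask``
    and ``w_in`` (inclusion indicator and summed geometric weight of the
    included markers) may be supplied by a caller that maintains them
    incrementally; otherwise they are rebuilt from ``current``.
    """
    p = ranking.p
    q_cap = q_cap if q_cap is not None else (cfg.q_cap or p)
    cur = current if isinstance(current, set) else set(int(j) for j in current)
    q = len(cur)
    if mask is None:
        mask = np.zeros(p, dtype=bool)
        if cur:
            mask[list(cur)] = True
    if w_in is None:
        w_in = float(np.sum(ranking.w[mask])) if q else 0.0
    n_ex = p - q
    u = ranking.uniform_mix
    w_ex = ranking.z_all - w_in

    pa, pr, ps = _eff_move_probs(q, p, q_cap, cfg)
    r = rng.random()
    if r < pa:
        k = _sample_excluded(mask, ranking, w_ex, rng)
        fwd = math.log(pa) + _add_log_density(ranking.w[k], w_ex, n_ex, u)
        pa2, pr2, ps2 = _eff_move_probs(q + 1, p, q_cap, cfg)
        rev = math.log(pr2) - math.log(q + 1)
        new = cur | {k}
    elif r < pa + pr:
        j = int(rng.choice(np.fromiter(cur, dtype=int, count=q)))
        fwd = math.log(pr) - math.log(q)
        pa2, pr2, ps2 = _eff_move_probs(q - 1, p, q_cap, cfg)
        rev = math.log(pa2) + _add_log_density(
            ranking.w[j], w_ex + ranking.w[j], n_ex + 1, u
        )
        new = cur - {j}
    else:
        j = int(rng.choice(np.fromiter(cur, dtype=int, count=q)))
        k = _sample_excluded(mask, ranking, w_ex, rng)
        fwd = math.log(ps) - math.log(q) + _add_log_density(
            ranking.w[k], w_ex, n_ex, u
        )
        w_ex_new = w_ex - ranking.w[k] + ranking.w[j]
        rev = math.log(ps) - math.log(q) + _add_log_density(
            ranking.w[j], w_ex_new, n_ex, u
        )
        new = (cur - {j}) | {k}
    return new, rev - fwd


# ---------------------------------------------------------------------------
# hyper proposal
# ---------------------------------------------------------------------------

def _reflect(x: float, lo: float, hi: float) -> float:
    if hi <= lo:
        return lo
    width = hi - lo
    t = (x - lo) % (2.0 * width)
    return lo + (width - abs(t - width))


def propose_hyper(
    current: HyperState,
    cfg: ProposalConfig,
    rng: np.random.Generator,
    p: int,
    s_a: float,
    s_b: float,
    pins: Optional[dict[str, float]] = None,
) -> tuple[HyperState, float]:
    """Symmetric reflected random walk on (h, rho, log pi); log-ratio 0."""
    pins = pins or {}
    step_lp = cfg.hyper_step_logpi
    if step_lp is None:
        step_lp = 0.1 * math.log(max(p, 2))
    lo_lp = -math.log(p)

    def walk(x: float, step: float, lo: float, hi: float) -> float:
        if step <= 0.0:
            return x
        return _reflect(x + step * (2.0 * rng.random() - 1.0), lo, hi)

    h = pins["h"] if "h" in pins else walk(current.h, cfg.hyper_step_h, 0.0, 1.0)
    rho = (pins["rho"] if "rho" in pins
           else walk(current.rho, cfg.hyper_step_rho, 0.0, 1.0))
    log_pi = (pins["log_pi"] if "log_pi" in pins
              else walk(current.log_pi, step_lp, lo_lp, 0.0))
    h = min(max(h, 1e-12), 1.0 - 1e-12)
    log_pi = min(log_pi, -1e-10)
    new = HyperState.from_h_rho_logpi(h, rho, log_pi, p, s_a, s_b)
    return new, 0.0


# ---------------------------------------------------------------------------
# posterior sample container
# ---------------------------------------------------------------------------

@dataclass
class PosteriorSamples:
    """Kept MCMC draws plus per-marker accumulators."""

    h: np.ndarray
    rho: np.ndarray
    log_pi: np.ndarray
    q: np.ndarray
    pve: np.ndarray
    pge: np.ndarray
    mu: np.ndarray
    tau: np.ndarray
    sigma_b2: np.ndarray
    inclusion_count: np.ndarray
    beta_sum: np.ndarray
    beta2_sum: np.ndarray
    acceptance_rates: dict[str, float]
    marker_ids: list[str]
    mode: str
    seed: int
    effects: Optional[list[tuple[np.ndarray, np.ndarray]]] = None
    reml: Optional[float] = None

    @property
    def n_kept(self) -> int:
        return self.pve.size

    def pip(self) -> np.ndarray:
        """Posterior inclusion probability per marker."""
        return self.inclusion_count / max(self.n_kept, 1)

    def beta_mean(self) -> np.ndarray:
        """Posterior mean effect per marker (zeros included)."""
        return self.beta_sum / max(self.n_kept, 1)

    def beta_mean_given_inclusion(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.inclusion_count > 0,
                self.beta_sum / np.maximum(self.inclusion_count, 1),
                0.0,
            )

    def abs_beta_mean_given_inclusion(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(
                self.inclusion_count > 0,
                self.beta2_sum / np.maximum(self.inclusion_count, 1),
                0.0,
            )

    def summary(self) -> dict[str, float]:
        return {
            "pve_mean": float(np.mean(self.pve)),
            "pve_sd": float(np.std(self.pve)),
            "pge_mean": float(np.mean(self.pge)),
            "pge_sd": float(np.std(self.pge)),
            "rho_mean": float(np.mean(self.rho)),
            "h_mean": float(np.mean(self.h)),
            "q_mean": float(np.mean(self.q)),
            "mu_mean": float(np.mean(self.mu)),
            "sigma_b2_mean": float(np.mean(self.sigma_b2)),
        }


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

class Sampler:
    """MH chain state with incrementally maintained likelihood caches."""

    def __init__(
        self,
        td: TransformedData,
        ranking: MarkerRanking,
        s_a: float,
        chain_cfg: ChainConfig,
        proposal_cfg: ProposalConfig,
        mode: str = "bslmm",
        pins: Optional[dict[str, float]] = None,
        sigma_b2_override: Optional[float] = None,
        rng: Optional[np.random.Generator] = None,
    ) -> None:
        if mode not in MODES:
            raise ValueError(f"unknown mode {mode!r}")
        self.td = td
        self.ranking = ranking
        self.s_a = s_a
        self.s_b = td.s_b
        self.p = td.p
        self.n = td.n
        self.cfg = proposal_cfg
        self.chain_cfg = chain_cfg
        self.mode = mode
        self.rng = rng if rng is not None else np.random.default_rng(chain_cfg.seed)
        self.q_cap = proposal_cfg.q_cap or min(self.n - 2, 300, self.p)
        self.sigma_b2_override = sigma_b2_override

        self.pins: dict[str, float] = dict(pins or {})
        self.gamma_pinned_empty = False
        if mode == "bvsr":
            self.pins.setdefault("rho", 1.0)
        elif mode == "lmm_bayes":
            self.pins.setdefault("rho", 0.0)
            self.pins.setdefault("log_pi", -math.log(self.p))
            self.gamma_pinned_empty = True
        elif mode == "bslmm_eb":
            # sparse effects plus a *fixed* polygenic variance component
            self.pins.setdefault("rho", 1.0)
            if sigma_b2_override is None:
                raise ValueError("bslmm_eb requires sigma_b2_override")

        self.accept_counts = {k: 0 for k in ("hyper", "add", "remove", "swap",
                                             "compound")}
        self.propose_counts = {k: 0 for k in self.accept_counts}

        # preallocated caches; F-order so column slices are contiguous.
        # Only the lower triangle of M is kept valid (dsyrk/dpotrf contract).
        cap = self.q_cap + 1
        self._Wt = np.empty((self.n, cap + 1), order="F")
        self._Wt[:, 0] = td.ones_t
        # double-buffered d-dependent caches: refreshes write into the spare
        # and swap, so a rejected hyper move restores by swapping back
        self._B = np.empty((self.n, cap + 1), order="F")  # sqrt(d)-weighted Wt
        self._B2 = np.empty((self.n, cap + 1), order="F")
        self._M = np.zeros((cap + 1, cap + 1))
        self._M2 = np.zeros((cap + 1, cap + 1))
        self._b = np.zeros(cap + 1)
        self._b2 = np.zeros(cap + 1)
        self.gam: list[int] = []
        self._pos: dict[int, int] = {}

        self._init_state()

    # -- state initialization ------------------------------------------------

    def _init_state(self) -> None:
        p = self.p
        e_log_pi = -0.5 * math.log(p)
        q0 = min(10, max(1, round(p * math.exp(e_log_pi))), self.q_cap)
        if self.gamma_pinned_empty:
            q0 = 0
        h0 = self.pins.get("h", 0.5)
        rho0 = self.pins.get("rho", 0.5)
        lp0 = self.pins.get("log_pi", e_log_pi)
        lp0 = min(max(lp0, -math.log(p)), -1e-10)
        for attempt in range(10):
            try:
                self.hyper = self._make_hyper(h0, rho0, lp0)
                gamma0 = [int(j) for j in self.ranking.order[:q0]]
                self._set_gamma_and_weights(gamma0, self.hyper.sigma_b2)
                self._set_current(*self._full_eval(self.hyper.sigma_a2))
                if math.isfinite(self._loglik):
                    return
            except np.linalg.LinAlgError:
                pass
            q0 = max(0, q0 // 2) if attempt < 9 else 0
        raise RuntimeError("failed to initialize MCMC at a finite-likelihood state")

    def _make_hyper(self, h: float, rho: float, log_pi: float) -> HyperState:
        st = HyperState.from_h_rho_logpi(h, rho, log_pi, self.p, self.s_a, self.s_b)
        if self.sigma_b2_override is not None:
            st = HyperState(h=st.h, rho=st.rho, log_pi=st.log_pi,
                            sigma_a2=st.sigma_a2,
                            sigma_b2=self.sigma_b2_override)
        return st

    # -- Gram cache maintenance ---------------------------------------------

    def _set_gamma_and_weights(self, gamma: list[int], sigma_b2: float) -> None:
        """Full rebuild of d, Wt, M, b and the inclusion mask."""
        td = self.td
        self.gam = list(gamma)
        self._pos = {k: i + 1 for i, k in enumerate(self.gam)}
        self._mask = np.zeros(self.p, dtype=bool)
        if self.gam:
            self._mask[self.gam] = True
        self._w_in = float(np.sum(self.ranking.w[self._mask]))
        q = len(self.gam)
        if q:
            self._Wt[:, 1:q + 1] = td.xt_matrix(self.gam)
        self._refresh_weights(sigma_b2)

    def _refresh_weights(self, sigma_b2: float) -> None:
        """Recompute the d-dependent parts for the *current* gamma.

        Writes into the spare buffers and swaps them in; the caller can
        undo by calling :meth:`_swap_buffers` again.
        """
        td = self.td
        self._d = 1.0 / (sigma_b2 * td.eigenvalues + 1.0)
        self._logdet_h = float(np.sum(np.log1p(sigma_b2 * td.eigenvalues)))
        self._sd = np.sqrt(self._d)
        self._sdy = self._sd * td.y_t
        self._yty_w = float(self._sdy @ self._sdy)
        q = len(self.gam)
        B = self._B2[:, :q + 1]
        np.multiply(self._Wt[:, :q + 1], self._sd[:, None], out=B)
        self._M2[:q + 1, :q + 1] = _dsyrk(1.0, B, trans=1, lower=1)
        self._b2[:q + 1] = self._sdy @ B
        self._swap_buffers()

    def _swap_buffers(self) -> None:
        self._B, self._B2 = self._B2, self._B
        self._M, self._M2 = self._M2, self._M
        self._b, self._b2 = self._b2, self._b

    def _add_marker(self, k: int) -> None:
        q = len(self.gam)
        xk = self.td.xt(k)
        self._Wt[:, q + 1] = xk
        sxk = self._sd * xk
        self._B[:, q + 1] = sxk
        self._M[q + 1, : q + 2] = sxk @ self._B[:, : q + 2]
        self._b[q + 1] = float(self._sdy @ sxk)
        self.gam.append(int(k))
        self._pos[int(k)] = q + 1
        self._mask[int(k)] = True
        self._w_in += float(self.ranking.w[int(k)])

    def _remove_marker(self, k: int) -> None:
        q = len(self.gam)
        i = self._pos[int(k)]
        if i != q:
            last = self.gam[q - 1]
            self._Wt[:, i] = self._Wt[:, q]
            self._B[:, i] = self._B[:, q]
            # row q lies entirely in the valid lower triangle
            row = self._M[q, : q + 1].copy()
            row[i] = self._M[q, q]
            self._M[i, : i + 1] = row[: i + 1]
            self._M[i:q + 1, i] = row[i:]
            self._b[i] = self._b[q]
            self.gam[i - 1] = last
            self._pos[last] = i
        self.gam.pop()
        del self._pos[int(k)]
        self._mask[int(k)] = False
        self._w_in -= float(self.ranking.w[int(k)])

    # -- likelihood ----------------------------------------------------------

    def _assemble_ll(self, q: int, logdet_a: float, S: float,
                     sigma_a2: float) -> float:
        n = self.n
        return (
            -0.5 * self._logdet_h
            - 0.5 * logdet_a
            - (0.5 * q * math.log(sigma_a2) if q else 0.0)
            - 0.5 * (n - 1) * math.log(S / 2.0)
            - 0.5 * (n - 1) * math.log(2.0 * math.pi)
            + math.lgamma(0.5 * (n - 1))
        )

    def _full_eval(self, sigma_a2: float):
        """Factorize A from the Gram caches; returns (ll, L, z, logdet_a, S).

        ``L`` is the lower Cholesky factor of ``A`` and ``z = L^{-1} b``,
        so ``S = y^T D y - z^T z`` and the GLS solution is ``L^{-T} z``.
        """
        q = 0 if sigma_a2 <= 0.0 else len(self.gam)
        A = self._M[: q + 1, : q + 1].copy()
        if q:
            # strided flat view of the diagonal starting at (1, 1)
            A.flat[q + 2:: q + 2] += 1.0 / sigma_a2
        L, info = _dpotrf(A, lower=1, overwrite_a=1, clean=0)
        if info != 0:
            raise np.linalg.LinAlgError("normal-equations matrix not PD")
        logdet_a = 2.0 * float(np.log(np.diag(L)).sum())
        z, info = _dtrtrs(L, self._b[: q + 1], lower=1)
        if info != 0:
            raise np.linalg.LinAlgError("triangular solve failed")
        S = self._yty_w - float(z @ z)
        if S <= 0.0:
            raise np.linalg.LinAlgError("non-positive residual quadratic form")
        ll = self._assemble_ll(q, logdet_a, S, sigma_a2)
        return ll, L, z, logdet_a, S

    def _set_current(self, ll, L, z, logdet_a, S) -> None:
        self._loglik = ll
        self._L = L
        self._z = z
        self._logdet_a = logdet_a
        self._S = S

    def _current_tuple(self):
        return (self._loglik, self._L, self._z, self._logdet_a, self._S)

    @staticmethod
    def _log1mpi(log_pi: float) -> float:
        om = -math.expm1(log_pi)
        return math.log(om) if om > 0 else -math.inf

    def _log_gamma_prior(self, q: int, log_pi: float) -> float:
        return q * log_pi + (self.p - q) * self._log1mpi(log_pi)

    # -- MH steps ------------------------------------------------------------

    def step(self) -> bool:
        """One MH iteration; returns whether the proposal was accepted."""
        if not self.gamma_pinned_empty and (
            self.rng.random() >= self.cfg.hyper_move_prob
        ):
            return self._gamma_step()
        return self._hyper_step()

    def _hyper_step(self) -> bool:
        self.propose_counts["hyper"] += 1
        cur = self.hyper
        # half the hyper moves touch only log pi: sigma_b2 is unchanged so
        # the O(n q^2) weighted-Gram rebuild is skipped entirely
        pins = self.pins
        if "log_pi" not in self.pins and self.rng.random() < 0.5:
            pins = {**self.pins, "h": cur.h, "rho": cur.rho}
        prop, _ = propose_hyper(cur, self.cfg, self.rng, self.p, self.s_a,
                                self.s_b, pins)
        prop = self._make_hyper(prop.h, prop.rho, prop.log_pi)
        q = len(self.gam)
        delta_gamma_prior = (
            self._log_gamma_prior(q, prop.log_pi)
            - self._log_gamma_prior(q, cur.log_pi)
        )
        saved_weights = None
        if prop.sigma_b2 != cur.sigma_b2:
            # scalar/reference saves only; the array buffers are swapped
            saved_weights = (self._d, self._sd, self._sdy, self._logdet_h,
                             self._yty_w)
            self._refresh_weights(prop.sigma_b2)
        try:
            state = self._full_eval(prop.sigma_a2)
        except np.linalg.LinAlgError:
            state = None
        ll = state[0] if state is not None else -math.inf
        if self._accept(ll - self._loglik + delta_gamma_prior):
            self.hyper = prop
            if state is not None:
                self._set_current(*state)
            self.accept_counts["hyper"] += 1
            return True
        if saved_weights is not None:
            (self._d, self._sd, self._sdy, self._logdet_h,
             self._yty_w) = saved_weights
            self._swap_buffers()
        return False

    def _propose_move(self):
        """Fast single-move proposal against the maintained inclusion state.

        Returns ``(kind, j_out, k_in, log_ratio)``; the density math mirrors
        :func:`propose_gamma` exactly.
        """
        rng = self.rng
        ranking = self.ranking
        cfg = self.cfg
        p = self.p
        q = len(self.gam)
        n_ex = p - q
        u = ranking.uniform_mix
        w_ex = ranking.z_all - self._w_in
        pa, pr, ps = _eff_move_probs(q, p, self.q_cap, cfg)
        r = rng.random()
        if r < pa:
            k = _sample_excluded(self._mask, ranking, w_ex, rng)
            fwd = math.log(pa) + _add_log_density(ranking.w[k], w_ex, n_ex, u)
            pa2, pr2, _ = _eff_move_probs(q + 1, p, self.q_cap, cfg)
            rev = math.log(pr2) - math.log(q + 1)
            return "add", -1, k, rev - fwd
        if r < pa + pr:
            j = self.gam[int(rng.integers(q))]
            fwd = math.log(pr) - math.log(q)
            pa2, _, _ = _eff_move_probs(q - 1, p, self.q_cap, cfg)
            rev = math.log(pa2) + _add_log_density(
                ranking.w[j], w_ex + ranking.w[j], n_ex + 1, u)
            return "remove", j, -1, rev - fwd
        j = self.gam[int(rng.integers(q))]
        k = _sample_excluded(self._mask, ranking, w_ex, rng)
        fwd = _add_log_density(ranking.w[k], w_ex, n_ex, u)
        rev = _add_log_density(
            ranking.w[j], w_ex - ranking.w[k] + ranking.w[j], n_ex, u)
        return "swap", j, k, rev - fwd

    def _gamma_step(self) -> bool:
        rng = self.rng
        sa2 = self.hyper.sigma_a2
        if rng.random() >= self.cfg.long_range_prob:
            kind, j_out, k_in, log_ratio = self._propose_move()
            self.propose_counts[kind] += 1
            dq = {"add": 1, "remove": -1, "swap": 0}[kind]
            delta_prior = dq * (
                self.hyper.log_pi - self._log1mpi(self.hyper.log_pi))
            if sa2 <= 0.0:
                # point-mass effects: likelihood ignores gamma entirely
                if self._accept(delta_prior + log_ratio):
                    if j_out >= 0:
                        self._remove_marker(j_out)
                    if k_in >= 0:
                        self._add_marker(k_in)
                    self.accept_counts[kind] += 1
                    return True
                return False
            if kind == "add":
                return self._try_add(k_in, delta_prior + log_ratio, kind)
            if kind == "remove":
                return self._try_remove(j_out, delta_prior + log_ratio, kind)
            return self._try_swap(j_out, k_in, delta_prior + log_ratio, kind)

        label = "compound"
        n_moves = int(rng.integers(2, self.cfg.compound_max + 1))
        cur_set = set(self.gam)
        new_set = cur_set
        log_ratio = 0.0
        for i in range(n_moves):
            if i == 0:
                new_set, lr = propose_gamma(
                    new_set, self.ranking, self.cfg, rng, q_cap=self.q_cap,
                    mask=self._mask, w_in=self._w_in,
                )
            else:
                new_set, lr = propose_gamma(new_set, self.ranking, self.cfg,
                                            rng, q_cap=self.q_cap)
            log_ratio += lr
        added = new_set - cur_set
        removed = cur_set - new_set
        dq = len(new_set) - len(cur_set)
        self.propose_counts[label] += 1
        if new_set == cur_set:
            self.accept_counts[label] += 1
            return True

        delta_prior = dq * (
            self.hyper.log_pi - self._log1mpi(self.hyper.log_pi)
        )

        if sa2 <= 0.0:
            if self._accept(delta_prior + log_ratio):
                for k in removed:
                    self._remove_marker(k)
                for k in added:
                    self._add_marker(k)
                self.accept_counts[label] += 1
                return True
            return False

        # compound: apply, evaluate fully, revert on reject
        for k in removed:
            self._remove_marker(k)
        for k in added:
            self._add_marker(k)
        try:
            state = self._full_eval(sa2)
        except np.linalg.LinAlgError:
            state = None
        ll = state[0] if state is not None else -math.inf
        if self._accept(ll - self._loglik + delta_prior + log_ratio):
            self._set_current(*state)
            self.accept_counts[label] += 1
            return True
        for k in added:
            self._remove_marker(k)
        for k in removed:
            self._add_marker(k)
        # the revert re-appends markers at the end, permuting the internal
        # column order, so the cached factor must be rebuilt to match
        self._set_current(*self._full_eval(sa2))
        return False

    def _try_add(self, k: int, log_extra: float, label: str) -> bool:
        """Rank-1 evaluation of adding marker k; state untouched on reject."""
        q = len(self.gam)
        sa2 = self.hyper.sigma_a2
        xk = self.td.xt(k)
        sxk = self._sd * xk
        v = sxk @ self._B[:, : q + 1]
        m = float(sxk @ sxk)
        b_new = float(self._sdy @ sxk)
        w, info = _dtrtrs(self._L, v, lower=1)
        if info != 0:
            return False
        s2 = m + 1.0 / sa2 - float(w @ w)
        if s2 <= 0.0:
            return False
        zeta = b_new - float(w @ self._z)
        S_new = self._S - zeta * zeta / s2
        if S_new <= 0.0:
            return False
        logdet_new = self._logdet_a + math.log(s2)
        ll_new = self._assemble_ll(q + 1, logdet_new, S_new, sa2)
        if not self._accept(ll_new - self._loglik + log_extra):
            return False
        # commit: extend the Gram caches and append a row to the factor
        self._Wt[:, q + 1] = xk
        self._B[:, q + 1] = sxk
        self._M[q + 1, : q + 1] = v
        self._M[q + 1, q + 1] = m
        self._b[q + 1] = b_new
        self.gam.append(int(k))
        self._pos[int(k)] = q + 1
        self._mask[int(k)] = True
        self._w_in += float(self.ranking.w[int(k)])
        L_new = np.zeros((q + 2, q + 2))
        L_new[: q + 1, : q + 1] = self._L[: q + 1, : q + 1]
        L_new[q + 1, : q + 1] = w
        sq = math.sqrt(s2)
        L_new[q + 1, q + 1] = sq
        z_new = np.empty(q + 2)
        z_new[: q + 1] = self._z
        z_new[q + 1] = zeta / sq
        self._set_current(ll_new, L_new, z_new, logdet_new, S_new)
        self.accept_counts[label] += 1
        return True

    def _try_swap(self, j_out: int, k_in: int, log_extra: float,
                  label: str) -> bool:
        """Rank-2 (Woodbury) evaluation of replacing marker j_out by k_in.

        Replacing row/column ``i`` of ``A`` is the symmetric rank-2 update
        ``A' = A + e_i u^T + u e_i^T``; the determinant and residual
        corrections need only two triangular solves against the cached
        factor, so the state is untouched on rejection.
        """
        q = len(self.gam)
        sa2 = self.hyper.sigma_a2
        i = self._pos[int(j_out)]
        xk = self.td.xt(k_in)
        sxk = self._sd * xk
        c = sxk @ self._B[:, : q + 1]       # Gram of new marker vs current W
        m_new = float(sxk @ sxk) + 1.0 / sa2
        b_new = float(self._sdy @ sxk)

        # current column i of A (lower-triangle storage, prior term on diag)
        a_i = np.empty(q + 1)
        a_i[: i + 1] = self._M[i, : i + 1]
        a_i[i + 1:] = self._M[i + 1: q + 1, i]
        a_i[i] += 1.0 / sa2

        u = c - a_i
        u[i] = (m_new - a_i[i]) / 2.0
        e = np.zeros(q + 1)
        e[i] = 1.0
        U2 = np.column_stack([e, u])
        P, info = _dtrtrs(self._L, U2, lower=1)
        if info != 0:
            return False
        M2 = P.T @ P
        # det(A') = det(A) * det(I + J M2) with J = [[0,1],[1,0]]
        C = np.array([[1.0 + M2[1, 0], M2[1, 1]],
                      [M2[0, 0], 1.0 + M2[0, 1]]])
        detC = float(C[0, 0] * C[1, 1] - C[0, 1] * C[1, 0])
        if detC <= 0.0:
            return False
        logdet_new = self._logdet_a + math.log(detC)
        # G = J + M2 for the Woodbury inverse correction
        G = np.array([[M2[0, 0], 1.0 + M2[0, 1]],
                      [1.0 + M2[1, 0], M2[1, 1]]])
        detG = float(G[0, 0] * G[1, 1] - G[0, 1] * G[1, 0])
        if detG == 0.0:
            return False
        gi = np.ascontiguousarray(P[:, 0])
        delta_b = b_new - self._b[i]
        w_b = self._z + delta_b * gi        # L^{-1} b'
        t = P.T @ w_b                       # U2^T A^{-1} b'
        Ginv_t = np.array([
            (G[1, 1] * t[0] - G[0, 1] * t[1]) / detG,
            (-G[1, 0] * t[0] + G[0, 0] * t[1]) / detG,
        ])
        quad = float(w_b @ w_b) - float(t @ Ginv_t)
        S_new = self._yty_w - quad
        if S_new <= 0.0:
            return False
        ll_new = self._assemble_ll(q, logdet_new, S_new, sa2)
        if not self._accept(ll_new - self._loglik + log_extra):
            return False
        self._remove_marker(j_out)
        self._add_marker(k_in)
        try:
            self._set_current(*self._full_eval(sa2))
        except np.linalg.LinAlgError:
            # detC > 0 does not guarantee A' is PD; back out
            self._remove_marker(k_in)
            self._add_marker(j_out)
            self._set_current(*self._full_eval(sa2))
            return False
        self.accept_counts[label] += 1
        return True

    def _try_remove(self, k: int, log_extra: float, label: str) -> bool:
        """Rank-1 evaluation of removing marker k via the inverse diagonal."""
        q = len(self.gam)
        sa2 = self.hyper.sigma_a2
        i = self._pos[int(k)]
        e = np.zeros(q + 1)
        e[i] = 1.0
        gvec, info = _dtrtrs(self._L, e, lower=1)
        if info != 0:
            return False
        aii = float(gvec @ gvec)          # (A^{-1})_{ii}
        alpha_i = float(gvec @ self._z)   # (A^{-1} b)_i
        S_new = self._S + alpha_i * alpha_i / aii
        logdet_new = self._logdet_a + math.log(aii)
        ll_new = self._assemble_ll(q - 1, logdet_new, S_new, sa2)
        if not self._accept(ll_new - self._loglik + log_extra):
            return False
        self._remove_marker(k)
        # the factor loses an interior row/column: refactorize from M
        self._set_current(*self._full_eval(sa2))
        self.accept_counts[label] += 1
        return True

    def _accept(self, log_alpha: float) -> bool:
        if log_alpha >= 0.0:
            return True
        if log_alpha == -math.inf:
            return False
        return self.rng.random() < math.exp(log_alpha)

    # -- effect draws --------------------------------------------------------

    def draw_effects(self):
        """Draw (tau, mu, beta, u_t, g_t) from the conditional at the state."""
        rng = self.rng
        n = self.n
        q_eff = 0 if self.hyper.sigma_a2 <= 0.0 else len(self.gam)
        tau = float(rng.gamma(0.5 * (n - 1), 2.0 / self._S))
        xi = rng.standard_normal(q_eff + 1)
        # theta = alpha + L^{-T} xi / sqrt(tau) = L^{-T}(z + xi / sqrt(tau))
        theta, info = _dtrtrs(self._L, self._z + xi / math.sqrt(tau),
                              lower=1, trans=1)
        if info != 0:
            raise np.linalg.LinAlgError("triangular solve failed")
        mu = float(theta[0])
        beta = theta[1:]
        r_t = self.td.y_t - self._Wt[:, : q_eff + 1] @ theta
        w = self.hyper.sigma_b2 * self.td.eigenvalues * self._d
        u_t = w * r_t
        if self.hyper.sigma_b2 > 0.0:
            u_t = u_t + np.sqrt(w / tau) * rng.standard_normal(n)
        g_t = self._Wt[:, 1: q_eff + 1] @ beta if q_eff else np.zeros(n)
        return tau, mu, beta, u_t, g_t

    def acceptance_rates(self) -> dict[str, float]:
        return {
            k: (self.accept_counts[k] / c if (c := self.propose_counts[k]) else
                float("nan"))
            for k in self.accept_counts
        }


def run_mcmc(
    geno: GenotypeMatrix,
    pheno: PhenotypeVector | np.ndarray,
    kin: Kinship,
    chain_cfg: Optional[ChainConfig] = None,
    proposal_cfg: Optional[ProposalConfig] = None,
    mode: str = "bslmm",
    pins: Optional[dict[str, float]] = None,
    sigma_b2_override: Optional[float] = None,
    precompute_transforms: bool = True,
) -> PosteriorSamples:
    """Run the full chain and collect posterior summaries.

    Individuals with missing phenotype are dropped (after the kinship has
    been built on the full genotyped set).  Modes: ``bslmm`` samples
    everything; ``bvsr`` pins rho = 1 (no random effect); ``lmm_bayes``
    pins gamma empty and rho = 0; ``bslmm_eb`` fixes the random-effect
    variance at its REML estimate and samples the sparse part.
    """
    chain_cfg = chain_cfg or ChainConfig()
    proposal_cfg = proposal_cfg or ProposalConfig()
    if not geno.centered:
        raise ValueError("genotypes must be imputed and centered")
    y = pheno if isinstance(pheno, PhenotypeVector) else PhenotypeVector(np.asarray(pheno, float))
    if np.any(y.missing_mask):
        keep = y.observed_idx
        geno = geno.subset_individuals(keep)
        kin = Kinship(K=kin.K[np.ix_(keep, keep)])
        y = PhenotypeVector(values=y.values[keep])

    td = transform_data(y, kin, geno)
    if precompute_transforms:
        td.precompute_all()
    order = rank_markers(td, geno, y)
    ranking = MarkerRanking(order, proposal_cfg.geometric_rank_param,
                            proposal_cfg.uniform_add_prob)

    reml_val = None
    if mode == "bslmm_eb" and sigma_b2_override is None:
        reml_val = reml_lmm(td)
        sigma_b2_override = reml_val.sigma_b2

    rng = np.random.default_rng(chain_cfg.seed)
    sampler = Sampler(td, ranking, geno.s_a, chain_cfg, proposal_cfg,
                      mode=mode, pins=pins,
                      sigma_b2_override=sigma_b2_override, rng=rng)

    n_keep = (chain_cfg.n_iter - chain_cfg.burn_in + chain_cfg.thin - 1) // chain_cfg.thin
    h_s = np.empty(n_keep)
    rho_s = np.empty(n_keep)
    lp_s = np.empty(n_keep)
    q_s = np.empty(n_keep, dtype=int)
    pve_s = np.empty(n_keep)
    pge_s = np.empty(n_keep)
    mu_s = np.empty(n_keep)
    tau_s = np.empty(n_keep)
    sb2_s = np.empty(n_keep)
    incl = np.zeros(td.p, dtype=np.int64)
    beta_sum = np.zeros(td.p)
    beta2_sum = np.zeros(td.p)
    effects = [] if chain_cfg.record_effects else None

    ones_t = td.ones_t
    k = 0
    for it in range(chain_cfg.n_iter):
        sampler.step()
        if it < chain_cfg.burn_in or (it - chain_cfg.burn_in) % chain_cfg.thin:
            continue
        tau, mu, beta, u_t, g_t = sampler.draw_effects()
        v = g_t + u_t
        v_tot = variance_in_transformed_basis(v, ones_t)
        if v_tot > 0.0:
            pve = v_tot / (v_tot + 1.0 / tau)
            pge = min(variance_in_transformed_basis(g_t, ones_t) / v_tot, 1.0)
        else:
            pve = 0.0
            pge = 0.0
        st = sampler.hyper
        h_s[k] = st.h
        rho_s[k] = st.rho
        lp_s[k] = st.log_pi
        q_s[k] = len(sampler.gam)
        pve_s[k] = pve
        pge_s[k] = pge
        mu_s[k] = mu
        tau_s[k] = tau
        sb2_s[k] = st.sigma_b2
        if beta.size:
            gidx = np.asarray(sampler.gam, dtype=int)
            incl[gidx] += 1
            np.add.at(beta_sum, gidx, beta)
            np.add.at(beta2_sum, gidx, np.abs(beta))
            if effects is not None:
                effects.append((gidx.copy(), beta.copy()))
        elif effects is not None:
            effects.append((np.empty(0, dtype=int), np.empty(0)))
        k += 1

    return PosteriorSamples(
        h=h_s[:k], rho=rho_s[:k], log_pi=lp_s[:k], q=q_s[:k],
        pve=pve_s[:k], pge=pge_s[:k], mu=mu_s[:k], tau=tau_s[:k],
        sigma_b2=sb2_s[:k],
        inclusion_count=incl, beta_sum=beta_sum, beta2_sum=beta2_sum,
        acceptance_rates=sampler.acceptance_rates(),
        marker_ids=list(geno.marker_ids), mode=mode, seed=chain_cfg.seed,
        effects=effects,
        reml=(reml_val.sigma_b2 if reml_val is not None else None),
    )


# ---------------------------------------------------------------------------
# output files
# ---------------------------------------------------------------------------

def save_hyp(samples: PosteriorSamples, path) -> None:
    """One row per kept draw: h, pve, rho, pge, pi, n_gamma."""
    with open(path, "w") as fh:
        fh.write("h\tpve\trho\tpge\tpi\tn_gamma\n")
        for i in range(samples.n_kept):
            fh.write(
                f"{samples.h[i]:.6g}\t{samples.pve[i]:.6g}\t"
                f"{samples.rho[i]:.6g}\t{samples.pge[i]:.6g}\t"
                f"{math.exp(samples.log_pi[i]):.6g}\t{samples.q[i]}\n"
            )


def save_param(samples: PosteriorSamples, path) -> None:
    """Per-marker: id, inclusion probability, mean beta, mean |beta| given in."""
    pip = samples.pip()
    bmean = samples.beta_mean()
    babs = samples.abs_beta_mean_given_inclusion()
    with open(path, "w") as fh:
        fh.write("id\tpip\tbeta_mean\tabs_beta_given_inclusion\n")
        for j, mid in enumerate(samples.marker_ids):
            fh.write(f"{mid}\t{pip[j]:.6g}\t{bmean[j]:.6g}\t{babs[j]:.6g}\n")
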