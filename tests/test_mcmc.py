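import math
from collections import defaultdict

import numpy as np
import pytest

from sparselmm.eigen_likelihood import log_marginal_likelihood, transform_data
from sparselmm.geno_io import (
    GenotypeMatrix,
    PhenotypeVector,
    compute_kinship,
    impute_and_center,
)
from sparselmm.mcmc import (
    ChainConfig,
    MarkerRanking,
    ProposalConfig,
    Sampler,
    _reflect,
    propose_gamma,
    propose_hyper,
    rank_markers,
    run_mcmc,
)
from sparselmm.model_core import HyperState
from sparselmm.simulate import simulate_genotypes, simulate_scenario1


class TestRankMarkers:
    def test_marker_equal_to_phenotype_ranks_first(self, rng):
        n, p = 30, 8
        X = rng.standard_normal((n, p))
        y = X[:, 5].copy()
        g = GenotypeMatrix(X, [f"m{j}" for j in range(p)], centered=True)
        order = rank_markers(None, g, PhenotypeVector(values=y))
        assert order[0] == 5

    def test_zero_variance_marker_ranks_last(self, rng):
        n, p = 30, 5
        X = rng.standard_normal((n, p))
        X[:, 2] = 1.0
        g = GenotypeMatrix(X, [f"m{j}" for j in range(p)], centered=True)
        y = rng.standard_normal(n)
        order = rank_markers(None, g, PhenotypeVector(values=y))
        assert order[-1] == 2

    def test_matches_bruteforce_f_statistics(self, rng):
        n, p = 40, 12
        X = rng.standard_normal((n, p))
        y = rng.standard_normal(n)
        g = GenotypeMatrix(X, [f"m{j}" for j in range(p)], centered=True)
        order = rank_markers(None, g, PhenotypeVector(values=y))
        fstats = []
        for j in range(p):
            x = X[:, j] - X[:, j].mean()
            yc = y - y.mean()
            bhat = (x @ yc) / (x @ x)
            rss = np.sum((yc - bhat * x) ** 2)
            fstats.append(bhat ** 2 * (x @ x) / (rss / (n - 2)))
        ref = np.lexsort((np.arange(p), -np.array(fstats)))
        np.testing.assert_array_equal(order, ref)


class TestProposeGamma:
    def _setup(self, p=4, g=0.4, u=0.2):
        ranking = MarkerRanking(np.arange(p), g, u)
        cfg = ProposalConfig()
        return ranking, cfg

    def test_proposals_land_in_valid_states(self, rng):
        ranking, cfg = self._setup()
        for _ in range(200):
            new, lr = propose_gamma({1}, ranking, cfg, rng)
            assert new <= set(range(4))
            assert math.isfinite(lr)

    def test_detailed_balance_by_enumeration(self):
        # empirical q(g'|g) against the returned Hastings log-ratio
        ranking, cfg = self._setup()
        rng = np.random.default_rng(0)
        n_draw = 120_000
        states = [frozenset(s) for s in
                  [set(), {0}, {1}, {2}, {3}, {0, 1}, {0, 2}, {1, 3}, {2, 3}]]
        freq = {}
        ratio = {}
        for s in states:
            counts = defaultdict(int)
            for _ in range(n_draw):
                new, lr = propose_gamma(set(s), ranking, cfg, rng)
                counts[frozenset(new)] += 1
                ratio[(s, frozenset(new))] = lr
            freq[s] = {t: c / n_draw for t, c in counts.items()}
        checked = 0
        for (s, t), lr in ratio.items():
            if s == t or t not in freq or s not in freq.get(t, {}):
                continue
            emp = math.log(freq[t][s] / freq[s][t])
            se = math.sqrt(
                (1 - freq[s][t]) / (freq[s][t] * n_draw)
                + (1 - freq[t][s]) / (freq[t][s] * n_draw))
            assert abs(emp - lr) < 4 * se + 0.02
            checked += 1
        assert checked >= 10

    def test_near_uniform_when_param_near_one(self):
        # from the empty set the only available move is an add
        ranking = MarkerRanking(np.arange(50), 0.9999, 0.0)
        cfg = ProposalConfig()
        rng = np.random.default_rng(1)
        counts = np.zeros(50)
        for _ in range(30000):
            new, _ = propose_gamma(set(), ranking, cfg, rng)
            counts[list(new)[0]] += 1
        props = counts / counts.sum()
        assert props.max() / props.min() < 1.6

    def test_add_fallback_when_all_included(self, rng):
        ranking, cfg = self._setup()
        full = set(range(4))
        for _ in range(50):
            new, _ = propose_gamma(full, ranking, cfg, rng)
            assert len(new) < 4 or new != full


class TestProposeHyper:
    def test_reflection(self):
        assert _reflect(1.04, 0.0, 1.0) == pytest.approx(0.96)
        assert _reflect(-0.03, 0.0, 1.0) == pytest.approx(0.03)
        assert _reflect(0.4, 0.0, 1.0) == pytest.approx(0.4)

    def test_log_ratio_always_zero(self, rng):
        cur = HyperState.from_h_rho_logpi(0.5, 0.5, -2.0, 100, 0.3, 1.0)
        for _ in range(100):
            _, lr = propose_hyper(cur, ProposalConfig(), rng, 100, 0.3, 1.0)
            assert lr == 0.0

    def test_symmetry_of_walk(self):
        rng = np.random.default_rng(0)
        cur = HyperState.from_h_rho_logpi(0.5, 0.5, -2.0, 100, 0.3, 1.0)
        cfg = ProposalConfig()
        hs = np.array([
            propose_hyper(cur, cfg, rng, 100, 0.3, 1.0)[0].h
            for _ in range(100_000)
        ])
        se = hs.std() / math.sqrt(len(hs))
        assert abs(hs.mean() - 0.5) < 3 * se

    def test_pins_respected(self, rng):
        cur = HyperState.from_h_rho_logpi(0.5, 1.0, -2.0, 100, 0.3, 1.0)
        for _ in range(20):
            new, _ = propose_hyper(cur, ProposalConfig(), rng, 100, 0.3, 1.0,
                                   pins={"rho": 1.0})
            assert new.rho == 1.0

    def test_stays_in_support(self, rng):
        p = 100
        cur = HyperState.from_h_rho_logpi(0.01, 0.99, -math.log(p) + 0.01,
                                          p, 0.3, 1.0)
        cfg = ProposalConfig(hyper_step_h=0.3, hyper_step_rho=0.3,
                             hyper_step_logpi=2.0)
        for _ in range(500):
            cur, _ = propose_hyper(cur, cfg, rng, p, 0.3, 1.0)
            assert 0 < cur.h < 1
            assert 0 <= cur.rho <= 1
            assert -math.log(p) <= cur.log_pi < 0


def _toy_chain(rng, n=40, p=30, **cfg_kw):
    raw = rng.integers(0, 3, (n, p)).astype(float)
    g = impute_and_center(GenotypeMatrix(raw, [f"m{j}" for j in range(p)]))
    kin = compute_kinship(g)
    beta = np.zeros(p)
    beta[:2] = [1.2, -0.9]
    y = PhenotypeVector(values=g.dosages @ beta + rng.standard_normal(n))
    return g, y, kin


class TestSamplerInternals:
    def test_cached_loglik_matches_reference(self, rng):
        g, y, kin = _toy_chain(rng)
        td = transform_data(y, kin, g)
        td.precompute_all()
        ranking = MarkerRanking(rank_markers(td, g, y), 0.3, 0.2)
        smp = Sampler(td, ranking, g.s_a,
                      ChainConfig(n_iter=100, burn_in=10, seed=1),
                      ProposalConfig(), rng=np.random.default_rng(1))
        for it in range(2000):
            smp.step()
            if it % 40 == 0:
                ref = log_marginal_likelihood(td, smp.gam, smp.hyper)
                assert smp._loglik == pytest.approx(ref.log_marginal,
                                                    abs=1e-8)

    def test_q_cap_respected(self, rng):
        g, y, kin = _toy_chain(rng)
        samples = run_mcmc(g, y, kin,
                           ChainConfig(n_iter=4000, burn_in=100, thin=1,
                                       seed=3),
                           ProposalConfig(q_cap=5), mode="bslmm")
        assert samples.q.max() <= 5


class TestRunMcmc:
    def test_determinism(self, rng):
        g, y, kin = _toy_chain(rng)
        cfg = ChainConfig(n_iter=3000, burn_in=500, thin=5, seed=42)
        a = run_mcmc(g, y, kin, cfg, ProposalConfig(), mode="bslmm")
        b = run_mcmc(g, y, kin, cfg, ProposalConfig(), mode="bslmm")
        np.testing.assert_array_equal(a.pve, b.pve)
        np.testing.assert_array_equal(a.h, b.h)
        np.testing.assert_array_equal(a.inclusion_count, b.inclusion_count)
        np.testing.assert_array_equal(a.beta_sum, b.beta_sum)

    def test_bvsr_pins(self, rng):
        g, y, kin = _toy_chain(rng)
        s = run_mcmc(g, y, kin, ChainConfig(n_iter=2000, burn_in=200, thin=5,
                                            seed=0),
                     ProposalConfig(), mode="bvsr")
        assert np.all(s.rho == 1.0)
        assert np.all(s.sigma_b2 == 0.0)

    def test_lmm_bayes_pins(self, rng):
        g, y, kin = _toy_chain(rng)
        s = run_mcmc(g, y, kin, ChainConfig(n_iter=2000, burn_in=200, thin=5,
                                            seed=0),
                     ProposalConfig(), mode="lmm_bayes")
        assert np.all(s.rho == 0.0)
        assert np.all(s.q == 0)
        assert np.all(s.pge == 0.0)

    def test_pve_pge_bounds(self, rng):
        g, y, kin = _toy_chain(rng)
        s = run_mcmc(g, y, kin, ChainConfig(n_iter=3000, burn_in=300, thin=3,
                                            seed=7),
                     ProposalConfig(), mode="bslmm")
        assert np.all((s.pve >= 0) & (s.pve <= 1))
        assert np.all((s.pge >= 0) & (s.pge <= 1))
        assert np.all(s.inclusion_count <= s.n_kept)

    def test_missing_phenotypes_dropped(self, rng):
        g, y, kin = _toy_chain(rng)
        vals = y.values.copy()
        vals[3] = np.nan
        y2 = PhenotypeVector(values=vals)
        s = run_mcmc(g, y2, kin, ChainConfig(n_iter=1000, burn_in=100, thin=5,
                                             seed=0),
                     ProposalConfig(), mode="bslmm")
        assert s.n_kept > 0

    def test_bslmm_eb_uses_reml_variance(self, rng):
        g, y, kin = _toy_chain(rng)
        s = run_mcmc(g, y, kin, ChainConfig(n_iter=2000, burn_in=200, thin=5,
                                            seed=1),
                     ProposalConfig(), mode="bslmm_eb")
        assert s.reml is not None
        assert np.all(s.sigma_b2 == s.reml)

    def test_effects_recording(self, rng):
        g, y, kin = _toy_chain(rng)
        s = run_mcmc(g, y, kin, ChainConfig(n_iter=1000, burn_in=100, thin=10,
                                            seed=2, record_effects=True),
                     ProposalConfig(), mode="bslmm")
        assert s.effects is not None
        assert len(s.effects) == s.n_kept

    def test_adaptivity_smoke(self):
        # sparse data drives rho up; dense polygenic data drives it down
        rng = np.random.default_rng(5)
        g = impute_and_center(simulate_genotypes(250, 600, (0.05, 0.5), 1,
                                                 rng))
        kin = compute_kinship(g)
        y_sparse, _ = simulate_scenario1(g, 5, 0.6, rng)
        y_poly, _ = simulate_scenario1(g, 600, 0.6, rng)
        cfg = ChainConfig(n_iter=20000, burn_in=5000, thin=10, seed=1)
        rho_sparse = np.median(run_mcmc(g, y_sparse, kin, cfg,
                                        ProposalConfig(), "bslmm").rho)
        rho_poly = np.median(run_mcmc(g, y_poly, kin, cfg,
                                      ProposalConfig(), "bslmm").rho)
        assert rho_sparse > rho_poly
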