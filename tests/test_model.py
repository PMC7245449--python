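"""Space-time binomial CAR model: full conditionals, sampler kernels,
diagnostics and smoothing behaviour."""

import numpy as np
import pytest
from scipy import stats

from malnutmap.model import (
    CountPanel, DiagnosticError, McmcConfig, ModelError, SpaceTimeCARModel,
    build_count_panel, car_full_conditional, dic, gelman_rubin, mc_error,
    metropolis_update_block, precision_gibbs_update, rw1_full_conditional,
)
from malnutmap.model import _ChainState
from malnutmap.simulate import make_district_graph, simulate_counts, simulate_truth
from malnutmap.spatial import build_adjacency


def _tree10(rng):
    """Random labelled tree on 10 nodes."""
    edges = [(int(rng.integers(1, k)), k) for k in range(2, 11)]
    return build_adjacency(edges, 10)


def _car_logdensity(phi, graph, tau):
    f = -0.5 * tau * sum(
        (phi[a - 1] - phi[b - 1]) ** 2 for a, b in graph.edge_list()
    )
    f += -0.5 * tau * sum(phi[i - 1] ** 2 for i in graph.isolated_nodes)
    return f


class TestCarFullConditional:
    def test_symmetric_neighbours_give_zero_mean(self):
        g = build_adjacency([(1, 2), (2, 3)], 3)
        phi = np.array([0.2, 0.0, -0.2])
        mean, _ = car_full_conditional(phi, 1, g, tau_phi=1.0)
        assert mean == pytest.approx(0.0)

    def test_variance_inverse_in_degree(self):
        g = build_adjacency([(1, 2), (1, 3), (1, 4), (1, 5)], 5)
        _, var = car_full_conditional(np.zeros(5), 0, g, tau_phi=1.0)
        assert var == pytest.approx(0.25)

    def test_matches_finite_difference_of_joint_density(self, rng):
        """Conditional mean/variance recovered from numerical derivatives of
        the pairwise-difference log-density on a 10-node tree."""
        g = _tree10(rng)
        tau = 2.7
        phi = rng.normal(size=10)
        h = 1e-4  # density is quadratic, so FD is exact up to roundoff
        for i in range(10):
            def f(v):
                p = phi.copy()
                p[i] = v
                return _car_logdensity(p, g, tau)
            g1 = (f(phi[i] + h) - f(phi[i] - h)) / (2 * h)
            g2 = (f(phi[i] + h) - 2 * f(phi[i]) + f(phi[i] - h)) / h**2
            mean_fd = phi[i] - g1 / g2
            var_fd = -1.0 / g2
            mean, var = car_full_conditional(phi, i, g, tau)
            assert mean == pytest.approx(mean_fd, abs=1e-6)
            assert var == pytest.approx(var_fd, abs=1e-6)

    def test_isolated_node_fallback(self):
        g = build_adjacency([(1, 2)], 3)
        mean, var = car_full_conditional(np.zeros(3), 2, g, tau_phi=4.0)
        assert (mean, var) == (0.0, 0.25)


class TestRw1FullConditional:
    def test_interior_average(self):
        mean, var = rw1_full_conditional(np.array([0.0, 9.9, 0.0]), 1, 3, 1.0)
        assert mean == pytest.approx(0.0)
        assert var == pytest.approx(0.5)

    def test_endpoint_single_neighbour(self):
        mean, var = rw1_full_conditional(np.array([0.0, 0.3, 0.1]), 0, 3, 2.0)
        assert mean == pytest.approx(0.3)
        assert var == pytest.approx(0.5)

    def test_matches_tridiagonal_precision_oracle(self, rng):
        J, tau = 5, 1.8
        gamma = rng.normal(size=J)
        K = np.zeros((J, J))  # RW1 structure matrix built explicitly
        for j in range(J - 1):
            K[j, j] += 1
            K[j + 1, j + 1] += 1
            K[j, j + 1] -= 1
            K[j + 1, j] -= 1
        Q = tau * K
        for j in range(J):
            mean, var = rw1_full_conditional(gamma, j, J, tau)
            assert var == pytest.approx(1.0 / Q[j, j], abs=1e-12)
            expect_mean = -(Q[j] @ gamma - Q[j, j] * gamma[j]) / Q[j, j]
            assert mean == pytest.approx(expect_mean, abs=1e-12)

    def test_single_period_rejected(self):
        with pytest.raises(ModelError):
            rw1_full_conditional(np.array([0.0]), 0, 1, 1.0)


class TestPrecisionGibbs:
    def test_zero_effects_draw_from_prior_scale(self, rng):
        draws = [precision_gibbs_update(np.zeros(6), "iid", 0.5, 0.0005, rng)
                 for _ in range(4000)]
        # Gamma(0.5 + 3, 0.0005): mean 3.5/0.0005
        expect = 3.5 / 0.0005
        assert np.mean(draws) == pytest.approx(expect, rel=0.1)

    def test_iid_posterior_parameters(self, rng):
        nu = np.array([1.0, -1.0, 0.0, 0.0])  # sum of squares 2, size 4
        draws = np.array([
            precision_gibbs_update(nu, "iid", 0.5, 0.0005, rng)
            for _ in range(20000)
        ])
        shape, rate = 0.5 + 2.0, 0.0005 + 1.0
        se = np.sqrt(shape) / rate / np.sqrt(len(draws))
        assert abs(draws.mean() - shape / rate) < 3 * se

    def test_car_quadratic_form_and_rank(self, rng):
        g = build_adjacency([(1, 2), (2, 3)], 4)  # node 4 isolated
        phi = np.array([1.0, 0.0, -1.0, 0.5])
        draws = np.array([
            precision_gibbs_update(phi, "car", 0.5, 0.0005, rng, graph=g)
            for _ in range(20000)
        ])
        q = 1.0 + 1.0 + 0.25  # edge diffs + isolated fallback
        r = (4 - 2) + 1  # nodes - components + isolated
        shape, rate = 0.5 + r / 2, 0.0005 + q / 2
        se = np.sqrt(shape) / rate / np.sqrt(len(draws))
        assert abs(draws.mean() - shape / rate) < 3 * se

    def test_rw1_rank(self, rng):
        gam = rng.normal(size=5)
        q = float(np.sum(np.diff(gam) ** 2))
        draws = np.array([
            precision_gibbs_update(gam, "rw1", 1.0, 0.01, rng)
            for _ in range(20000)
        ])
        shape, rate = 1.0 + 2.0, 0.01 + q / 2
        se = np.sqrt(shape) / rate / np.sqrt(len(draws))
        assert abs(draws.mean() - shape / rate) < 3 * se


def _gelman_rubin_oracle(chains):
    """Textbook between/within formula, loop-coded."""
    m = len(chains)
    n = len(chains[0])
    means = [sum(c) / n for c in chains]
    grand = sum(means) / m
    B = n / (m - 1) * sum((mu - grand) ** 2 for mu in means)
    W = sum(sum((x - mu) ** 2 for x in c) / (n - 1) for c, mu in zip(chains, means)) / m
    var_plus = (n - 1) / n * W + B / n
    return np.sqrt(var_plus / W)


class TestDiagnostics:
    def test_identical_chains_rhat_one(self, rng):
        c = rng.normal(size=2000)
        assert gelman_rubin([c, c.copy()]) == pytest.approx(1.0, abs=1e-3)

    def test_disjoint_chains_rhat_large(self, rng):
        a = rng.normal(size=500)
        assert gelman_rubin([a, a + 50.0]) > 10.0

    def test_matches_textbook_oracle(self, rng):
        chains = [rng.normal(size=400), rng.normal(0.2, 1.3, size=400),
                  rng.normal(-0.1, 0.8, size=400)]
        assert gelman_rubin(chains) == pytest.approx(
            _gelman_rubin_oracle([c.tolist() for c in chains]), abs=1e-10)

    def test_close_to_arviz_on_stationary_chains(self, rng):
        import arviz as az

        chains = np.stack([rng.normal(size=1000), rng.normal(size=1000)])
        ours = gelman_rubin(list(chains))
        theirs = float(az.rhat(chains[None].transpose(1, 2, 0)[..., 0]))
        assert abs(ours - theirs) < 0.05

    def test_single_chain_rejected(self, rng):
        with pytest.raises(DiagnosticError):
            gelman_rubin([rng.normal(size=100)])

    def test_mc_error_iid_theory(self, rng):
        errs, sds = [], []
        for _ in range(30):
            d = rng.normal(size=4000)
            errs.append(mc_error(d))
            sds.append(d.std(ddof=1))
        ratio = np.mean(errs) / (np.mean(sds) / np.sqrt(4000))
        assert 0.8 < ratio < 1.2

    def test_mc_error_constant_draws(self):
        assert mc_error(np.full(1000, 3.3)) == pytest.approx(0.0, abs=1e-12)

    def test_mc_error_root_n_scaling(self, rng):
        r1 = np.mean([mc_error(rng.normal(size=2000)) for _ in range(40)])
        r2 = np.mean([mc_error(rng.normal(size=4000)) for _ in range(40)])
        assert r2 / r1 == pytest.approx(1 / np.sqrt(2), rel=0.15)

    def test_mc_error_too_few_draws(self):
        with pytest.raises(DiagnosticError):
            mc_error(np.arange(10.0))


class TestDic:
    def _panel(self):
        return CountPanel("o", Y=[[3, 5], [2, 8]], n=[[10, 12], [9, 20]])

    def test_degenerate_posterior_has_zero_pd(self):
        panel = self._panel()
        pi = np.full((50, 2, 2), 0.3)
        d, pD = dic(pi, panel)
        assert pD == pytest.approx(0.0, abs=1e-8)

    def test_deviance_matches_scipy_at_fixed_draws(self):
        panel = self._panel()
        pi0 = np.array([[0.25, 0.4], [0.2, 0.45]])
        d, pD = dic(pi0[None], panel)
        hand = -2 * stats.binom.logpmf(panel.Y, panel.n, pi0).sum()
        assert d == pytest.approx(hand, abs=1e-8)  # pD = 0, DIC = deviance

    def test_interaction_term_increases_pd_on_interaction_free_data(self):
        g = make_district_graph(8, seed=0)
        truth = simulate_truth(g, 3, alpha=-1.5, tau_nu=1e8, seed=3)
        panel = simulate_counts(truth, np.full((8, 3), 250.0), seed=4)
        base_cfg = McmcConfig(n_chains=2, burn_in=500, n_keep=1500, thin=1,
                              seed=5, fix_nu=True, extend_until_converged=False)
        full_cfg = McmcConfig(n_chains=2, burn_in=500, n_keep=1500, thin=1,
                              seed=5, extend_until_converged=False)
        m = SpaceTimeCARModel(panel, g)
        _, pD_base = m.fit(base_cfg).dic()
        _, pD_full = m.fit(full_cfg).dic()
        assert pD_full > pD_base


class TestBuildCountPanel:
    @pytest.mark.parametrize("p, n, expect", [(0.10, 50, 5), (0.0, 40, 0),
                                              (0.105, 48, 5)])
    def test_rounding(self, p, n, expect):
        panel = build_count_panel([[p]], [[n]])
        assert panel.Y[0, 0] == expect

    def test_invalid_prevalence(self):
        with pytest.raises(ModelError):
            build_count_panel([[1.2]], [[10]])

    def test_panel_invariants(self):
        with pytest.raises(ModelError):
            CountPanel("o", Y=[[5]], n=[[3]])


class TestSamplerMechanics:
    def _model(self, I=6, J=3, seed=0):
        g = make_district_graph(I, seed=seed)
        truth = simulate_truth(g, J, seed=seed)
        panel = simulate_counts(truth, np.full((I, J), 80.0), seed=seed + 1)
        return SpaceTimeCARModel(panel, g)

    def test_zero_proposal_always_accepted(self):
        m = self._model()
        cfg = McmcConfig(burn_in=10, n_keep=10, thin=1, seed=0,
                         proposal_sds={"alpha": 0.0, "phi": 0.0,
                                       "gamma": 0.0, "nu": 0.0})
        state = _ChainState(m, cfg, np.random.default_rng(0), 0.1)
        for block in ("alpha", "phi", "gamma", "nu"):
            _, rate = metropolis_update_block(state, block)
            assert rate == 1.0

    def test_sum_to_zero_after_every_sweep(self):
        m = self._model()
        cfg = McmcConfig(burn_in=10, n_keep=10, thin=1, seed=0)
        state = _ChainState(m, cfg, np.random.default_rng(1), 0.5)
        for _ in range(25):
            state.sweep()
            assert abs(state.phi.sum()) < 1e-10
            assert abs(state.gamma.sum()) < 1e-10

    def test_recentring_preserves_linear_predictor(self):
        m = self._model()
        cfg = McmcConfig(burn_in=10, n_keep=10, thin=1, seed=0)
        state = _ChainState(m, cfg, np.random.default_rng(2), 0.5)
        for _ in range(10):
            state.sweep()
            recomputed = (state.alpha + state.phi[:, None]
                          + state.gamma[None, :] + state.nu)
            assert np.allclose(recomputed, state.eta, atol=1e-10)

    def test_acceptance_rates_reasonable_after_adaptation(self):
        g = make_district_graph(52, seed=0)
        truth = simulate_truth(g, 5, seed=1)
        panel = simulate_counts(truth, np.full((52, 5), 60.0), seed=2)
        res = SpaceTimeCARModel(panel, g).fit(
            McmcConfig(n_chains=1, burn_in=800, n_keep=800, thin=1, seed=3,
                       extend_until_converged=False))
        for block, rate in res.acceptance_rates.items():
            assert 0.1 <= rate <= 0.7, (block, rate)

    def test_empty_cell_smoothed_between_neighbours(self):
        # path graph; middle district unobserved in wave 1, neighbours
        # strongly observed at 10% and 30%
        g = build_adjacency([(1, 2), (2, 3)], 3)
        n = np.full((3, 2), 600.0)
        n[1, 0] = 0.0
        Y = np.round(np.array([[0.10, 0.10], [0.0, 0.20], [0.30, 0.30]]) * n)
        panel = CountPanel("o", Y=Y, n=n)
        res = SpaceTimeCARModel(panel, g).fit(
            McmcConfig(n_chains=2, burn_in=800, n_keep=2000, thin=1, seed=4,
                       extend_until_converged=False))
        med = res.pi_median()
        assert med[0, 0] < med[1, 0] < med[2, 0]

    def test_all_zero_counts_pull_prevalence_to_zero(self):
        g = make_district_graph(6, seed=0)
        panel = CountPanel("o", Y=np.zeros((6, 2)), n=np.full((6, 2), 100.0))
        res = SpaceTimeCARModel(panel, g).fit(
            McmcConfig(n_chains=1, burn_in=500, n_keep=1000, thin=1, seed=5,
                       extend_until_converged=False))
        assert res.pi_median().max() < 0.03

    def test_graph_panel_mismatch_rejected(self):
        g = make_district_graph(6, seed=0)
        with pytest.raises(ModelError):
            SpaceTimeCARModel(CountPanel("o", Y=np.zeros((4, 2)),
                                         n=np.ones((4, 2))), g)

    def test_single_cell_model_rejected(self):
        g = build_adjacency([], 1)
        with pytest.raises(ModelError):
            SpaceTimeCARModel(CountPanel("o", Y=[[1.0]], n=[[5.0]]), g)

    def test_single_district_posterior_matches_quadrature(self):
        """With one district and gamma, nu frozen, the posterior of
        inverse-logit(alpha + phi) is a flat-prior binomial posterior;
        compare against 1-D grid quadrature."""
        g = build_adjacency([], 1)
        panel = CountPanel("o", Y=[[7.0, 9.0]], n=[[40.0, 45.0]])
        cfg = McmcConfig(n_chains=2, burn_in=1000, n_keep=8000, thin=1, seed=6,
                         fix_gamma=True, fix_nu=True, fixed_tau_phi=1.0,
                         fixed_tau_gamma=1.0, fixed_tau_nu=1.0,
                         extend_until_converged=False)
        res = SpaceTimeCARModel(panel, g).fit(cfg)
        eta = np.linspace(-6, 4, 4001)
        p = 1 / (1 + np.exp(-eta))
        logpost = 16 * np.log(p) + (85 - 16) * np.log1p(-p)
        w = np.exp(logpost - logpost.max())
        w /= w.sum()
        expect = float((w * p).sum())
        got = float(res.pi_draws[:, 0, 0].mean())
        assert got == pytest.approx(expect, abs=0.01)


class TestResultsApi:
    def test_summary_and_frames(self):
        g = make_district_graph(6, seed=0)
        truth = simulate_truth(g, 3, seed=0)
        panel = simulate_counts(truth, np.full((6, 3), 50.0), seed=1,
                                outcome="stunting")
        res = SpaceTimeCARModel(panel, g).fit(
            McmcConfig(n_chains=2, burn_in=300, n_keep=600, thin=1, seed=2,
                       extend_until_converged=False))
        text = res.summary()
        assert "stunting" in text and "DIC" in text
        frame = res.summary_frame()
        assert len(frame) == 18
        assert (frame["bci_low"] <= frame["median"]).all()
        assert (frame["median"] <= frame["bci_high"]).all()
        assert res.gelman_rubin("alpha") > 0
        assert res.mc_error("alpha") >= 0
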