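"""Sampler correctness: priors, kernel, proposals, posterior summaries."""

import math

import numpy as np
import pytest
from scipy import integrate
from scipy.stats import expon, ks_2samp

from popsplit.genealogy import EventGenealogy, Node, genealogy_log_density
from popsplit.likelihood import MutationModel, pruning_loglike
from popsplit.mcmc import (
    ChainConfig,
    PriorSpec,
    initial_genealogy,
    log_posterior_kernel,
    propose_genealogy,
    run_chain,
    summarize_posterior,
)
from popsplit.popmodel import ParameterSet, PopulationModel
from popsplit.simulate import SimulationConfig, simulate_dataset, simulate_genealogy

SINGLE = PopulationModel(("p1",), (2,))


def two_tip_tree(t):
    nodes = {0: Node(0, 0.0, 0, parent=2, name="p1_0"),
             1: Node(1, 0.0, 0, parent=2, name="p1_1"),
             2: Node(2, t, 0, children=[0, 1])}
    return EventGenealogy(nodes, 2)


class TestPriorSpec:
    def test_uniform_logpdf_and_bounds(self):
        pr = PriorSpec("uniform", 0.0, 2.0)
        assert pr.logpdf(1.0) == pytest.approx(math.log(0.5))
        assert pr.logpdf(3.0) == -math.inf

    def test_truncated_exponential_sampling_matches_logpdf(self):
        pr = PriorSpec("exponential", 0.0, 0.06, mean=0.02)
        rng = np.random.default_rng(1)
        draws = np.array([pr.sample(rng) for _ in range(20000)])
        assert draws.max() <= 0.06 and draws.min() >= 0.0
        # normalisation of the truncated density
        z, _ = integrate.quad(lambda x: math.exp(pr.logpdf(x)), 0, 0.06)
        assert z == pytest.approx(1.0, abs=1e-8)
        # analytic truncated-exponential mean
        m = 0.02 - 0.06 * math.exp(-3) / (1 - math.exp(-3))
        assert draws.mean() == pytest.approx(m, abs=3 * draws.std() / 140)


class TestSummarizePosterior:
    def test_constant_samples_flagged_degenerate(self):
        s = summarize_posterior(np.full(200, 3.0), "c")
        assert s.degenerate and s.mode == 3.0 and s.std_width == 0.0

    def test_uniform_percentiles(self):
        rng = np.random.default_rng(2)
        s = summarize_posterior(rng.uniform(0, 1, 100_000), support=(0, 1))
        assert s.p2_5 == pytest.approx(0.025, abs=0.005)
        assert s.p97_5 == pytest.approx(0.975, abs=0.005)

    def test_exponential_quantiles_match_analytic(self):
        rng = np.random.default_rng(3)
        x = rng.exponential(1.0, 100_000)
        s = summarize_posterior(x, support=(0, float(x.max())), bins=400)
        assert s.p2_5 == pytest.approx(expon.ppf(0.025), rel=0.1)
        assert s.p97_5 == pytest.approx(expon.ppf(0.975), rel=0.03)
        # standardized width definition
        assert s.std_width == pytest.approx((s.p97_5 - s.p2_5) / s.mode)

    def test_needs_enough_samples(self):
        with pytest.raises(ValueError):
            summarize_posterior(np.arange(50))


class TestLogPosteriorKernel:
    PRIORS = {"theta_p1": PriorSpec("uniform", 0.001, 0.1)}

    def test_prior_boundary(self):
        g = two_tip_tree(0.01)
        inside = ParameterSet(theta=(0.001 + 1e-6,))
        outside = ParameterSet(theta=(0.001 - 1e-6,))
        assert np.isfinite(log_posterior_kernel([g], inside, None, SINGLE, self.PRIORS))
        assert log_posterior_kernel([g], outside, None, SINGLE, self.PRIORS) == -math.inf

    def test_doubling_identical_loci_doubles_data_term(self):
        g = two_tip_tree(0.01)
        p = ParameterSet(theta=(0.02,))
        aln = {"p1_0": "ACGTAC", "p1_1": "ACGTAT"}
        one = log_posterior_kernel([g], p, [aln], SINGLE, self.PRIORS)
        two = log_posterior_kernel([g, g.copy()], p, [aln, dict(aln)], SINGLE,
                                   self.PRIORS)
        prior = self.PRIORS["theta_p1"].logpdf(0.02)
        assert two - prior == pytest.approx(2 * (one - prior), rel=1e-12)

    def test_two_tip_matches_quadrature(self):
        """Marginal likelihood from the kernel's factors equals direct 1-D
        integration of Kingman(t) x pruning(t) over the coalescence time."""
        p = ParameterSet(theta=(0.02,))
        mm = MutationModel()
        aln = {"p1_0": "ACGTACGTAA", "p1_1": "ACGAACGTAT"}

        def joint(t):
            g = two_tip_tree(t)
            return math.exp(genealogy_log_density(g, p, SINGLE)
                            + pruning_loglike(g, aln, mm))

        direct, _ = integrate.quad(joint, 0, 1.0, limit=200)
        # Monte-Carlo over genealogies drawn from the coalescent prior
        rng = np.random.default_rng(4)
        t = rng.exponential(0.01, 40000)
        mc = np.mean([math.exp(pruning_loglike(two_tip_tree(ti), aln, mm))
                      for ti in t])
        assert direct == pytest.approx(mc, rel=0.05)


class TestGenealogyProposal:
    def test_proposals_always_valid(self):
        model = PopulationModel(("a", "b"), (3, 3),
                                migration_edges={(0, 1), (1, 0)},
                                divergence_edges={(1, 0)})
        params = ParameterSet(theta=(0.01, 0.01), mig={(0, 1): 50.0, (1, 0): 50.0},
                              div_mean={(1, 0): 0.01}, div_sd={(1, 0): 0.003})
        rng = np.random.default_rng(5)
        g = simulate_genealogy(SimulationConfig(model, params, seed=6),
                               np.random.default_rng(6))
        for _ in range(2000):
            out = propose_genealogy(g, params, model, rng)
            if out is None:
                continue
            g2, log_h = out
            assert np.isfinite(log_h)
            assert g2.validate(model) == []
            g = g2  # wander without MH: stays valid everywhere

    def test_stationary_distribution_matches_direct_simulation(self):
        """Prior-only MH over genealogies must match the simulator, which
        samples f(G | rho) exactly."""
        model = PopulationModel(("a", "b"), (2, 2),
                                migration_edges={(0, 1), (1, 0)},
                                divergence_edges={(1, 0)})
        params = ParameterSet(theta=(0.01, 0.01), mig={(0, 1): 50.0, (1, 0): 50.0},
                              div_mean={(1, 0): 0.01}, div_sd={(1, 0): 0.003})
        rng = np.random.default_rng(7)
        g = simulate_genealogy(SimulationConfig(model, params, seed=8),
                               np.random.default_rng(8))
        lf = genealogy_log_density(g, params, model)
        ts = []
        for i in range(12000):
            out = propose_genealogy(g, params, model, rng)
            if out is not None:
                g2, log_h = out
                lf2 = genealogy_log_density(g2, params, model)
                d = lf2 - lf + log_h
                if d >= 0 or rng.uniform() < math.exp(max(d, -700)):
                    g, lf = g2, lf2
            if i % 5 == 0:
                ts.append(g.nodes[g.root].time)
        rng2 = np.random.default_rng(9)
        direct = []
        for _ in range(3000):
            gg = simulate_genealogy(SimulationConfig(model, params, seed=8), rng2)
            direct.append(gg.nodes[gg.root].time)
        assert ks_2samp(ts, direct).pvalue > 0.001

    def test_fixed_data_posterior_matches_grid(self):
        """2-tip coalescence-time posterior from genealogy-only MH equals
        the 1-D grid posterior Kingman(t) x pruning(t)."""
        p = ParameterSet(theta=(0.02,))
        mm = MutationModel()
        aln = {"p1_0": "A" * 80 + "C" * 10, "p1_1": "A" * 80 + "T" * 10}
        rng = np.random.default_rng(10)
        g = two_tip_tree(0.01)
        lpost = (genealogy_log_density(g, p, SINGLE)
                 + pruning_loglike(g, aln, mm))
        ts = []
        for i in range(15000):
            out = propose_genealogy(g, p, SINGLE, rng)
            if out is not None:
                g2, log_h = out
                lp2 = (genealogy_log_density(g2, p, SINGLE)
                       + pruning_loglike(g2, aln, mm))
                d = lp2 - lpost + log_h
                if d >= 0 or rng.uniform() < math.exp(max(d, -700)):
                    g, lpost = g2, lp2
            if i % 5 == 0:
                ts.append(g.nodes[g.root].time)
        grid = np.linspace(1e-6, 0.4, 4000)
        logw = np.array([
            genealogy_log_density(two_tip_tree(t), p, SINGLE)
            + pruning_loglike(two_tip_tree(t), aln, mm) for t in grid])
        w = np.exp(logw - logw.max())
        w /= w.sum()
        mean_grid = float(np.dot(grid, w))
        var_grid = float(np.dot((grid - mean_grid) ** 2, w))
        assert np.mean(ts) == pytest.approx(mean_grid, abs=3 * math.sqrt(var_grid / 200))
        # compare the sampled CDF against the grid CDF at the quartiles
        cdf = np.cumsum(w)
        for q in (0.25, 0.5, 0.75):
            t_q = grid[np.searchsorted(cdf, q)]
            assert np.mean(np.asarray(ts) <= t_q) == pytest.approx(q, abs=0.1)


class TestRunChain:
    def test_prior_recovery_small_im_model(self):
        model = PopulationModel(("pop1", "pop2"), (3, 3),
                                migration_edges={(0, 1), (1, 0)},
                                divergence_edges={(1, 0)})
        priors = {
            "theta_pop1": PriorSpec("uniform", 0.001, 0.05),
            "theta_pop2": PriorSpec("uniform", 0.001, 0.05),
            "M_pop1_to_pop2": PriorSpec("uniform", 0.0, 200.0),
            "M_pop2_to_pop1": PriorSpec("uniform", 0.0, 200.0),
            "tau_pop2_pop1": PriorSpec("uniform", 1e-6, 0.06),
            "sigma_pop2_pop1": PriorSpec("uniform", 1e-8, 0.01),
        }
        res = run_chain(None, model, priors,
                        ChainConfig(length=30000, burnin=3000, thin=5, seed=2))
        for i, name in enumerate(res.param_names):
            pr = priors[name]
            med = (np.median(res.samples[:, i]) - pr.lower) / (pr.upper - pr.lower)
            assert abs(med - 0.5) < 0.15, f"{name}: median quantile {med:.2f}"

    def test_reproducible_given_seed(self):
        model = PopulationModel(("a", "b"), (2, 2), divergence_edges={(1, 0)})
        priors = {
            "theta_a": PriorSpec("uniform", 0.001, 0.05),
            "theta_b": PriorSpec("uniform", 0.001, 0.05),
            "tau_b_a": PriorSpec("uniform", 1e-6, 0.02),
            "sigma_b_a": PriorSpec("uniform", 1e-8, 0.005),
        }
        cfg = ChainConfig(length=2000, burnin=200, thin=4, seed=42)
        r1 = run_chain(None, model, priors, cfg)
        r2 = run_chain(None, model, priors, cfg)
        np.testing.assert_array_equal(r1.samples, r2.samples)

    def test_recovery_with_data_smoke(self):
        model = PopulationModel(("pop1", "pop2"), (6, 6),
                                divergence_edges={(1, 0)})
        truth = ParameterSet(theta=(0.01, 0.01), div_mean={(1, 0): 0.002},
                             div_sd={(1, 0): 2e-4})
        _, alns = simulate_dataset(SimulationConfig(model, truth, loci=3,
                                                    sites=500, seed=31))
        priors = {
            "theta_pop1": PriorSpec("uniform", 1e-6, 0.1),
            "theta_pop2": PriorSpec("uniform", 1e-6, 0.1),
            "tau_pop2_pop1": PriorSpec("exponential", 1e-8, 0.0075, mean=0.0025),
            "sigma_pop2_pop1": PriorSpec("uniform", 1e-8, 5e-4),
        }
        res = run_chain(alns, model, priors,
                        ChainConfig(length=6000, burnin=1500, thin=5, seed=13))
        s = res.summaries["tau_pop2_pop1"]
        # crude but meaningful: posterior concentrates within the right
        # order of magnitude of the simulated truth
        assert 0.0004 < s.mode < 0.006
        assert np.isfinite(res.log_posterior_trace).all()

    def test_initial_genealogy_label_repair(self):
        model = PopulationModel(("pop1", "pop2"), (4, 4),
                                divergence_edges={(1, 0)})
        truth = ParameterSet(theta=(0.01, 0.01), div_mean={(1, 0): 0.002},
                             div_sd={(1, 0): 2e-4})
        _, alns = simulate_dataset(SimulationConfig(model, truth, loci=1,
                                                    sites=400, seed=77))
        g = initial_genealogy(alns[0], model, truth, np.random.default_rng(0))
        assert g.validate(model) == []
        assert {n.name for n in g.tips()} == set(alns[0])
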