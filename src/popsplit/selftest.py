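"""Fast built-in invariant checks, runnable from the command line.

Each check exercises a core identity of the method on small inputs:
cumulative-hazard closed form vs quadrature, competing-risks
normalisation, Kingman closed forms on simulated trees, and a short
prior-recovery chain.  All checks are deterministic given the seed.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import integrate

__all__ = ["selftest"]


def _check_cum_hazard(seed: int, corrupt: bool = False):
    from popsplit.hazards import DivergenceDistribution, div_cum_hazard, div_hazard
    rng = np.random.default_rng(seed)
    worst = 0.0
    worst_at = None
    for _ in range(10):
        tau = 10 ** rng.uniform(-3, -1.5)
        sd = tau * 10 ** rng.uniform(-1, 0.3)
        d = DivergenceDistribution(tau, sd)
        t0 = rng.uniform(0, 2 * tau)
        u = rng.uniform(0.1 * sd, 3 * sd)
        closed = float(div_cum_hazard(t0, u, d))
        if corrupt:
            closed *= 1.01  # test hook: deliberately wrong closed form
        num, _ = integrate.quad(lambda t: div_hazard(t, d), t0, t0 + u,
                                epsabs=1e-14, epsrel=1e-12)
        err = abs(closed - num) / max(abs(num), 1e-300)
        if err > worst:
            worst, worst_at = err, (tau, sd, t0, u)
    return worst <= 1e-8, f"max rel err {worst:.2e} at {worst_at}"


def _check_xi_normalisation(seed: int):
    from popsplit.hazards import DivergenceDistribution, xi_event_probabilities
    rng = np.random.default_rng(seed + 1)
    worst = 0.0
    for _ in range(10):
        d = DivergenceDistribution(10 ** rng.uniform(-3, -2),
                                   10 ** rng.uniform(-4, -2))
        lam_c = rng.uniform(0, 500)
        lam_m = rng.uniform(0, 300)
        xi = xi_event_probabilities(lam_c, lam_m, rng.uniform(0, 0.01), d)
        worst = max(worst, abs(sum(xi) - 1.0))
    return worst <= 1e-6, f"max |sum-1| = {worst:.2e}"


def _check_kingman(seed: int):
    from popsplit.genealogy import genealogy_log_density
    from popsplit.popmodel import ParameterSet, PopulationModel
    from popsplit.simulate import SimulationConfig, simulate_genealogy
    model = PopulationModel(("p1",), (8,))
    params = ParameterSet(theta=(0.02,))
    rng = np.random.default_rng(seed + 2)
    cfg = SimulationConfig(model, params, seed=seed)
    worst = 0.0
    for _ in range(50):
        g = simulate_genealogy(cfg, rng)
        times = sorted(n.time for n in g.nodes.values() if n.children)
        closed, t0, k = 0.0, 0.0, 8
        for t in times:
            closed += math.log(2 / 0.02) - (t - t0) * k * (k - 1) / 0.02
            t0, k = t, k - 1
        worst = max(worst, abs(genealogy_log_density(g, params, model) - closed))
    return worst <= 1e-8, f"max |log-density error| = {worst:.2e}"


def _check_prior_recovery(seed: int):
    from popsplit.mcmc import ChainConfig, PriorSpec, run_chain
    from popsplit.popmodel import PopulationModel
    model = PopulationModel(("a", "b"), (2, 2), divergence_edges={(1, 0)})
    priors = {
        "theta_a": PriorSpec("uniform", 0.005, 0.05),
        "theta_b": PriorSpec("uniform", 0.005, 0.05),
        "tau_b_a": PriorSpec("uniform", 1e-6, 0.05),
        "sigma_b_a": PriorSpec("uniform", 1e-8, 0.01),
    }
    res = run_chain(None, model, priors,
                    ChainConfig(length=16000, burnin=2000, thin=4, seed=seed))
    worst = 0.0
    for i, name in enumerate(res.param_names):
        pr = priors[name]
        med = (np.median(res.samples[:, i]) - pr.lower) / (pr.upper - pr.lower)
        worst = max(worst, abs(med - 0.5))
    return worst <= 0.2, f"max |median quantile - 0.5| = {worst:.2f}"


def selftest(seed: int = 1, _corrupt_cum_hazard: bool = False) -> dict:
    """Run the invariant suite; returns {check: (passed, detail)}."""
    return {
        "cumulative_hazard_quadrature": _check_cum_hazard(seed, _corrupt_cum_hazard),
        "xi_normalisation": _check_xi_normalisation(seed),
        "kingman_closed_form": _check_kingman(seed),
        "prior_recovery": _check_prior_recovery(seed),
    }
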