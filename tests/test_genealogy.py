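"""Genealogy density: Kingman closed forms, event factors, serialization."""

import math

import numpy as np
import pytest
from scipy import integrate

from popsplit.genealogy import (
    DIVERGENCE,
    MIGRATION,
    Event,
    EventGenealogy,
    IntervalState,
    Node,
    coalescent_rate,
    from_newick,
    genealogy_log_density,
    interval_log_density,
    iter_interval_states,
    migration_total_rate,
    to_newick,
)
from popsplit.hazards import DivergenceDistribution, div_cum_hazard, div_log_hazard
from popsplit.popmodel import ParameterSet, PopulationModel
from popsplit.simulate import SimulationConfig, simulate_genealogy

SINGLE = PopulationModel(("p1",), (2,))
IM = PopulationModel(("pop1", "pop2"), (2, 2),
                     migration_edges={(0, 1), (1, 0)},
                     divergence_edges={(1, 0)})


def two_tip_tree(t, pop=0, model=SINGLE):
    nodes = {
        0: Node(0, 0.0, pop, parent=2, name="a"),
        1: Node(1, 0.0, pop, parent=2, name="b"),
        2: Node(2, t, pop, children=[0, 1]),
    }
    return EventGenealogy(nodes, 2)


class TestRates:
    def test_coalescent_rate_values(self):
        assert coalescent_rate(2, 0.02) == pytest.approx(100.0)
        assert coalescent_rate(1, 0.02) == 0.0
        assert coalescent_rate(5, 0.01) == pytest.approx(2000.0)
        with pytest.raises(ValueError):
            coalescent_rate(2, 0.0)

    def test_migration_total_rate(self):
        p = ParameterSet(theta=(0.01, 0.01), mig={(1, 0): 50.0, (0, 1): 10.0})
        assert migration_total_rate((2, 1), p, IM) == pytest.approx(2 * 50 + 1 * 10)
        p0 = ParameterSet(theta=(0.01,))
        assert migration_total_rate((3,), p0, SINGLE) == 0.0


class TestIntervalDensity:
    def test_simple_coalescence_interval(self):
        p = ParameterSet(theta=(0.02,))
        s = IntervalState(0.0, 0.01, (2,), ("coalescence", 0))
        # exponential density lambda e^{-lambda u} with lambda = 100
        assert interval_log_density(s, p, SINGLE) == pytest.approx(
            math.log(100 * math.exp(-1.0)))

    def test_impossible_migration_is_minus_inf(self):
        p = ParameterSet(theta=(0.01, 0.01), mig={(0, 1): 0.0})
        s = IntervalState(0.0, 0.01, (1, 1), ("migration", 1, 0))
        assert interval_log_density(s, p, IM) == -math.inf

    def test_divergence_interval_matches_hand_rolled_terms(self):
        # two derived lineages at risk; interval ends with one divergence
        p = ParameterSet(theta=(0.01, 0.01), mig={(0, 1): 100.0},
                         div_mean={(1, 0): 0.005}, div_sd={(1, 0): 0.005})
        s = IntervalState(0.0, 0.005, (0, 2), ("divergence", 1, 0))
        d = DivergenceDistribution(0.005, 0.005)
        lam_cm = 2 * 1 / 0.01 + 2 * 100.0
        lam_d, _ = integrate.quad(
            lambda t: math.exp(float(div_log_hazard(t, d))), 0, 0.005,
            epsabs=1e-13)
        expected = (-0.005 * lam_cm - 2 * lam_d
                    + float(div_log_hazard(0.005, d)))
        assert interval_log_density(s, p, IM) == pytest.approx(expected, rel=1e-8)


class TestGenealogyDensity:
    def test_two_tip_kingman_closed_form(self):
        p = ParameterSet(theta=(0.02,))
        g = two_tip_tree(0.01)
        assert genealogy_log_density(g, p, SINGLE) == pytest.approx(
            math.log((2 / 0.02) * math.exp(-2 * 0.01 / 0.02)))

    def test_three_tip_kingman_closed_form(self):
        p = ParameterSet(theta=(0.02,))
        m = PopulationModel(("p1",), (3,))
        t1, t2 = 0.004, 0.011
        nodes = {
            0: Node(0, 0.0, 0, parent=3, name="a"),
            1: Node(1, 0.0, 0, parent=3, name="b"),
            2: Node(2, 0.0, 0, parent=4, name="c"),
            3: Node(3, t1, 0, parent=4, children=[0, 1]),
            4: Node(4, t2, 0, children=[3, 2]),
        }
        g = EventGenealogy(nodes, 4)
        closed = (math.log(6 / 0.02) - 6 * t1 / 0.02
                  - math.log(3)  # specific pair among three
                  + math.log(2 / 0.02) - 2 * (t2 - t1) / 0.02)
        # our convention: per-pair factor 2/theta with survival k(k-1)/theta
        expected = (math.log(2 / 0.02) - 6 * t1 / 0.02
                    + math.log(2 / 0.02) - 2 * (t2 - t1) / 0.02)
        assert genealogy_log_density(g, p, m) == pytest.approx(expected)
        assert closed == pytest.approx(expected)  # identical by algebra

    def test_density_integrates_to_one_two_tips(self):
        p = ParameterSet(theta=(0.02,))
        val, _ = integrate.quad(
            lambda t: math.exp(genealogy_log_density(two_tip_tree(t), p, SINGLE)),
            0, 0.5, limit=200, epsabs=1e-10)
        assert val == pytest.approx(1.0, abs=1e-6)

    def test_kingman_equivalence_on_simulated_trees(self):
        model = PopulationModel(("p1",), (10,))
        p = ParameterSet(theta=(0.02,))
        cfg = SimulationConfig(model, p, seed=42)
        rng = np.random.default_rng(42)
        worst = 0.0
        for _ in range(200):
            g = simulate_genealogy(cfg, rng)
            times = sorted(n.time for n in g.nodes.values() if n.children)
            closed, t0, k = 0.0, 0.0, 10
            for t in times:
                closed += math.log(2 / 0.02) - (t - t0) * k * (k - 1) / 0.02
                t0, k = t, k - 1
            worst = max(worst, abs(genealogy_log_density(g, p, model) - closed))
        assert worst <= 1e-8

    def test_event_genealogy_matches_bruteforce_interval_product(self):
        # hand-build: 2 tips in pop2, 2 migrations + 2 divergences, coalesce in pop1
        p = ParameterSet(theta=(0.01, 0.02), mig={(0, 1): 30.0, (1, 0): 20.0},
                         div_mean={(1, 0): 0.006}, div_sd={(1, 0): 0.003})
        nodes = {
            0: Node(0, 0.0, 1, parent=2, name="a", events=[
                Event(0.001, MIGRATION, 1, 0),
                Event(0.002, MIGRATION, 0, 1),
                Event(0.005, DIVERGENCE, 1, 0),
            ]),
            1: Node(1, 0.0, 1, parent=2, name="b", events=[
                Event(0.006, DIVERGENCE, 1, 0),
            ]),
            2: Node(2, 0.008, 0, children=[0, 1]),
        }
        g = EventGenealogy(nodes, 2)
        m = PopulationModel(("pop1", "pop2"), (0, 2),
                            migration_edges={(0, 1), (1, 0)},
                            divergence_edges={(1, 0)})
        assert g.validate(m) == []

        # brute force, written independently of the production interval walk
        d = DivergenceDistribution(0.006, 0.003)
        bounds = [0.0, 0.001, 0.002, 0.005, 0.006, 0.008]
        counts = [(0, 2), (1, 1), (0, 2), (1, 1), (2, 0)]
        events = [("mig", 30.0), ("mig", 20.0), ("div", None), ("div", None),
                  ("coal", 0.01)]
        expected = 0.0
        for (lo, hi), (k0, k1), (kind, val) in zip(
                zip(bounds, bounds[1:]), counts, events):
            u = hi - lo
            lam_c = k0 * (k0 - 1) / 0.01 + k1 * (k1 - 1) / 0.02
            lam_m = k1 * 30.0 + k0 * 20.0
            expected += -u * (lam_c + lam_m) - k1 * float(div_cum_hazard(lo, u, d))
            if kind == "mig":
                expected += math.log(val)
            elif kind == "div":
                expected += float(div_log_hazard(hi, d))
            else:
                expected += math.log(2 / val)
        assert genealogy_log_density(g, p, m) == pytest.approx(expected, rel=1e-10)

    def test_invalid_genealogy_raises_with_violations(self):
        g = two_tip_tree(0.01)
        g.nodes[0].events.append(Event(0.005, MIGRATION, 0, 1))
        p = ParameterSet(theta=(0.02,))
        with pytest.raises(ValueError, match="inconsistent|undeclared"):
            genealogy_log_density(g, p, SINGLE)

    def test_small_sd_marginal_matches_hard_split(self):
        """Integrating out near-degenerate switch times recovers the
        sharp-boundary isolation-model density for a 2-tip genealogy."""
        tau, sd = 0.006, 8e-5
        theta = (0.01, 0.01)
        p = ParameterSet(theta=theta, div_mean={(1, 0): tau},
                         div_sd={(1, 0): sd})
        m = PopulationModel(("pop1", "pop2"), (0, 2), divergence_edges={(1, 0)})
        t_c = 0.009  # coalescence after the split

        def dens(s1, s2):
            ev_lo, ev_hi = sorted([s1, s2])
            nodes = {
                0: Node(0, 0.0, 1, parent=2, name="a",
                        events=[Event(ev_lo, DIVERGENCE, 1, 0)]),
                1: Node(1, 0.0, 1, parent=2, name="b",
                        events=[Event(ev_hi, DIVERGENCE, 1, 0)]),
                2: Node(2, t_c, 0, children=[0, 1]),
            }
            return math.exp(genealogy_log_density(EventGenealogy(nodes, 2), p, m))

        marg, _ = integrate.dblquad(dens, tau - 6 * sd, tau + 6 * sd,
                                    lambda x: tau - 6 * sd, lambda x: tau + 6 * sd,
                                    epsabs=1e-10)
        # the square covers both (lineage, time) assignments, which matches
        # summing over the two equally likely labelled genealogies
        # hard split: coalescence in pop2 (rate 2/theta) blocked until tau,
        # then both lineages sit in pop1
        hard = math.exp(-2 / theta[1] * tau) * (2 / theta[0]) * math.exp(
            -2 / theta[0] * (t_c - tau))
        assert marg == pytest.approx(hard, rel=0.03)


class TestNewickRoundTrip:
    def test_round_trip_preserves_density(self):
        m = PopulationModel(("pop1", "pop2"), (4, 4),
                            migration_edges={(0, 1), (1, 0)},
                            divergence_edges={(1, 0)})
        p = ParameterSet(theta=(0.01, 0.01), mig={(0, 1): 80.0, (1, 0): 80.0},
                         div_mean={(1, 0): 0.008}, div_sd={(1, 0): 0.002})
        cfg = SimulationConfig(m, p, seed=7)
        rng = np.random.default_rng(7)
        for _ in range(10):
            g = simulate_genealogy(cfg, rng)
            g2 = from_newick(to_newick(g))
            assert g2.validate(m) == []
            assert genealogy_log_density(g2, p, m) == pytest.approx(
                genealogy_log_density(g, p, m), rel=1e-9, abs=1e-9)

    def test_tip_names_and_events_survive(self):
        g = two_tip_tree(0.01)
        g.nodes[0].events.append(Event(0.004, MIGRATION, 0, 1))
        g.nodes[0].events.append(Event(0.007, DIVERGENCE, 1, 0))
        g2 = from_newick(to_newick(g))
        tips = {n.name: n for n in g2.tips()}
        assert set(tips) == {"a", "b"}
        evs = tips["a"].events
        assert [e.kind for e in evs] == [MIGRATION, DIVERGENCE]
        assert evs[0].time == pytest.approx(0.004)
        assert evs[1].to_pop == 0


class TestIntervalDecomposition:
    def test_counts_update_through_events(self):
        m = PopulationModel(("pop1", "pop2"), (0, 2), divergence_edges={(1, 0)})
        nodes = {
            0: Node(0, 0.0, 1, parent=2, name="a",
                    events=[Event(0.004, DIVERGENCE, 1, 0)]),
            1: Node(1, 0.0, 1, parent=2, name="b",
                    events=[Event(0.005, DIVERGENCE, 1, 0)]),
            2: Node(2, 0.007, 0, children=[0, 1]),
        }
        g = EventGenealogy(nodes, 2)
        states = list(iter_interval_states(g, m))
        assert [s.counts for s in states] == [(0, 2), (1, 1), (2, 0)]
        assert states[-1].event == ("coalescence", 0)
        assert sum(s.u for s in states) == pytest.approx(0.007)
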