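"""Metropolis–Hastings sampling of genealogies and parameters.

The posterior p(rho | D) is explored by alternating two move classes:

* **Genealogy moves.**  One lineage segment (the branch above a randomly
  chosen non-root node) is detached and its backward path is re-simulated
  against the fixed remainder of the tree using competing draws —
  exponential waiting times for coalescence and migration, survival
  inversion for the divergence hazard — until it re-coalesces.  Above the
  time of the background root the remaining root lineage becomes active
  too and the pair is simulated jointly until it merges into a new root.
  The Hastings ratio uses the exact path densities of the old and new
  segments against the same background.

* **Parameter moves.**  Sliding-window proposals (reflected at the prior
  bounds) for every Theta, M, divergence mean and divergence spread, with
  window widths tuned during burn-in toward 20–40% acceptance.

Posterior distributions are summarised by histograms over the prior
support; the point estimate is the midpoint of the highest bin after
3-bin smoothing, and the spread is reported as the standardised
credibility width (p97.5 - p2.5) / mode.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import linkage

from popsplit.genealogy import (
    DIVERGENCE,
    MIGRATION,
    Event,
    EventGenealogy,
    Node,
    iter_interval_states,
)
from popsplit.hazards import DivergenceDistribution, sample_div_time
from popsplit.likelihood import (CompressedAlignment, MutationModel,
                                  encode_alignment, pruning_loglike)
from popsplit.popmodel import ParameterSet, PopulationModel

__all__ = [
    "PriorSpec",
    "ChainConfig",
    "PosteriorSummary",
    "ChainResult",
    "default_priors",
    "log_posterior_kernel",
    "propose_genealogy",
    "run_chain",
    "summarize_posterior",
    "initial_genealogy",
    "population_map_from_names",
]


# ---------------------------------------------------------------------------
# priors and chain configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PriorSpec:
    """Exponential (mean, truncated to [lower, upper]) or uniform prior."""

    kind: str  # "uniform" | "exponential"
    lower: float
    upper: float
    mean: float | None = None  # exponential only

    def __post_init__(self):
        if self.kind not in ("uniform", "exponential"):
            raise ValueError(f"unknown prior kind {self.kind!r}")
        if not (0 <= self.lower < self.upper):
            raise ValueError("prior bounds must satisfy 0 <= lower < upper")
        if self.kind == "exponential" and (self.mean is None or self.mean <= 0):
            raise ValueError("exponential prior needs a positive mean")

    def logpdf(self, x: float) -> float:
        if not (self.lower <= x <= self.upper):
            return -math.inf
        if self.kind == "uniform":
            return -math.log(self.upper - self.lower)
        z = math.exp(-self.lower / self.mean) - math.exp(-self.upper / self.mean)
        return -x / self.mean - math.log(self.mean * z)

    def sample(self, rng: np.random.Generator) -> float:
        if self.kind == "uniform":
            return float(rng.uniform(self.lower, self.upper))
        lo = math.exp(-self.lower / self.mean)
        hi = math.exp(-self.upper / self.mean)
        u = rng.uniform()
        return -self.mean * math.log(lo - u * (lo - hi))


@dataclass(frozen=True)
class ChainConfig:
    """MCMC run settings."""

    length: int = 20000
    burnin: int = 5000
    thin: int = 10
    bins: int = 1500
    seed: int = 0
    genealogy_weight: float = 0.6

    def __post_init__(self):
        if not (0 <= self.burnin < self.length):
            raise ValueError("burn-in must be shorter than the chain")
        if self.bins < 10:
            raise ValueError("need at least 10 histogram bins")
        if not (0 < self.genealogy_weight < 1):
            raise ValueError("genealogy_weight must be in (0,1)")


@dataclass
class PosteriorSummary:
    """Histogram summary of one parameter's posterior sample."""

    name: str
    mode: float
    p2_5: float
    p97_5: float
    std_width: float
    mean: float
    ess: float
    hist: np.ndarray
    edges: np.ndarray
    degenerate: bool = False


@dataclass
class ChainResult:
    summaries: dict
    samples: np.ndarray          # (n_kept, n_params)
    param_names: list
    acceptance: dict
    seed: int
    log_posterior_trace: np.ndarray


# ---------------------------------------------------------------------------
# parameter bookkeeping
# ---------------------------------------------------------------------------

def _param_entries(model: PopulationModel):
    """Ordered (name, kind, key) for every free parameter of the model."""
    entries = []
    for i, lab in enumerate(model.population_labels):
        entries.append((f"theta_{lab}", "theta", i))
    for (j, i) in sorted(model.migration_edges):
        entries.append((
            f"M_{model.population_labels[j]}_to_{model.population_labels[i]}",
            "mig", (j, i)))
    for (der, anc) in sorted(model.divergence_edges):
        lab = f"{model.population_labels[der]}_{model.population_labels[anc]}"
        entries.append((f"tau_{lab}", "div_mean", (der, anc)))
        entries.append((f"sigma_{lab}", "div_sd", (der, anc)))
    return entries


def _get_param(params: ParameterSet, kind: str, key):
    if kind == "theta":
        return params.theta[key]
    return getattr(params, kind)[key]


def _set_param(params: ParameterSet, kind: str, key, value: float) -> ParameterSet:
    if kind == "theta":
        theta = list(params.theta)
        theta[key] = value
        return params.replace(theta=tuple(theta))
    d = dict(getattr(params, kind))
    d[key] = value
    return params.replace(**{kind: d})


def default_priors(model: PopulationModel, theta_upper: float = 0.1,
                   tau_upper: float = 0.06, tau_mean: float | None = None,
                   mig_upper: float = 1000.0,
                   sigma_upper: float | None = None) -> dict:
    """Reasonable default priors: uniform for Theta, M and sigma, and a
    bounded exponential for the divergence mean (a vague prior whose upper
    bound should be set ~3x beyond the oldest divergence considered).
    The sigma prior range is kept small relative to tau_upper because wide
    spread priors interact with immigration-rate estimation."""
    priors = {}
    sigma_upper = sigma_upper if sigma_upper is not None else tau_upper / 4
    for name, kind, _ in _param_entries(model):
        if kind == "theta":
            priors[name] = PriorSpec("uniform", 1e-6, theta_upper)
        elif kind == "mig":
            priors[name] = PriorSpec("uniform", 0.0, mig_upper)
        elif kind == "div_mean":
            priors[name] = PriorSpec("exponential", 1e-8, tau_upper,
                                     mean=tau_mean or tau_upper / 3)
        else:
            priors[name] = PriorSpec("uniform", 1e-8, sigma_upper)
    return priors


# ---------------------------------------------------------------------------
# cached genealogy sufficient statistics
# ---------------------------------------------------------------------------

class _GenealogyStats:
    """Per-locus sufficient statistics of f(G | rho).

    log f = sum_i [n_coal_i log(2/Theta_i) - a_i / Theta_i]
          + sum_e [n_mig_e log M_e - b_e M_e]
          + sum_d [sum_events log hazard(t) - sum_slices k Lambda]
    so Theta/M updates need no tree walk and divergence updates only a
    vectorised hazard evaluation.
    """

    __slots__ = ("n_coal", "a_coal", "n_mig", "b_mig", "div_slices", "div_events")

    def __init__(self, g: EventGenealogy, model: PopulationModel,
                 div_edges, mig_edges):
        n = model.n_populations
        self.n_coal = np.zeros(n)
        self.a_coal = np.zeros(n)
        self.n_mig = {e: 0 for e in mig_edges}
        self.b_mig = {e: 0.0 for e in mig_edges}
        slices = {e: [] for e in div_edges}
        events = {e: [] for e in div_edges}
        for st in iter_interval_states(g, model):
            for i, k in enumerate(st.counts):
                if k > 1:
                    self.a_coal[i] += st.u * k * (k - 1)
            for (j, i) in mig_edges:
                if st.counts[i] > 0:
                    self.b_mig[(j, i)] += st.u * st.counts[i]
            for e in div_edges:
                k = st.counts[e[0]]
                if k > 0 and st.u > 0:
                    slices[e].append((st.t0, st.u, k))
            ev = st.event
            if ev[0] == "coalescence":
                self.n_coal[ev[1]] += 1
            elif ev[0] == "migration":
                self.n_mig[(ev[2], ev[1])] += 1
            else:
                events[(ev[1], ev[2])].append(st.t0 + st.u)
        self.div_slices = {
            e: tuple(np.array(v).T) if v else (np.empty(0),) * 3
            for e, v in slices.items()}
        self.div_events = {e: np.array(v) for e, v in events.items()}

    def log_density(self, params: ParameterSet) -> float:
        total = 0.0
        for i, th in enumerate(params.theta):
            total += self.n_coal[i] * math.log(2.0 / th) - self.a_coal[i] / th
        for e, n in self.n_mig.items():
            m = params.mig.get(e, 0.0)
            if n > 0:
                if m <= 0:
                    return -math.inf
                total += n * math.log(m)
            total -= m * self.b_mig[e]
        for e, (t0s, us, ks) in self.div_slices.items():
            d = DivergenceDistribution(params.div_mean[e], params.div_sd[e],
                                       params.b1)
            if len(t0s):
                lam = d._log_sf(t0s) - d._log_sf(t0s + us)
                total -= float(np.dot(ks, lam))
            times = self.div_events[e]
            if len(times):
                if np.any(times >= d.b1):
                    return -math.inf
                z = (times - d.tau_mean) / d.tau_sd
                log_h = (-0.5 * z * z - 0.5 * math.log(2 * math.pi)
                         - math.log(d.tau_sd) - d._log_sf(times))
                total += float(np.sum(log_h))
        return total


def genealogy_log_density_cached(g: EventGenealogy, params: ParameterSet,
                                 model: PopulationModel) -> float:
    return _GenealogyStats(g, model, sorted(model.divergence_edges),
                           sorted(model.migration_edges)).log_density(params)


def log_posterior_kernel(genealogies, params: ParameterSet, data,
                         model: PopulationModel, priors: dict,
                         mutation: MutationModel | None = None) -> float:
    """log p(rho) + sum_loci [log f(G_l | rho) + log p(D_l | G_l)].

    ``data`` may be None (prior-only kernel without the sequence term).
    Returns -inf outside the prior support.
    """
    total = 0.0
    for name, kind, key in _param_entries(model):
        total += priors[name].logpdf(_get_param(params, kind, key))
        if total == -math.inf:
            return -math.inf
    mutation = mutation or MutationModel()
    for idx, g in enumerate(genealogies):
        total += genealogy_log_density_cached(g, params, model)
        if data is not None:
            total += pruning_loglike(g, data[idx], mutation)
    return total


# ---------------------------------------------------------------------------
# genealogy proposal: detach one lineage, re-simulate its path
# ---------------------------------------------------------------------------

class _Branch:
    __slots__ = ("node_id", "t_start", "t_end", "labels")

    def __init__(self, node_id, t_start, t_end, start_label, events):
        self.node_id = node_id
        self.t_start = t_start
        self.t_end = t_end  # inf for the background root lineage
        # label path: [(time_from, label)], first entry at t_start
        self.labels = [(t_start, start_label)]
        for ev in events:
            self.labels.append((ev.time, ev.to_pop))

    def label_at(self, t: float) -> int:
        lab = self.labels[0][1]
        for tt, l in self.labels:
            if tt <= t:
                lab = l
            else:
                break
        return lab

    def alive_at(self, t: float) -> bool:
        return self.t_start <= t < self.t_end


class _Background:
    """The genealogy minus the focal branch, as a piecewise-constant
    per-population lineage-count profile plus branch lookup."""

    def __init__(self, g: EventGenealogy, x_id: int, n_pops: int):
        x = g.nodes[x_id]
        p = g.nodes[x.parent]
        sib = next(c for c in p.children if c != x_id)
        branches = []
        for n in g.nodes.values():
            if n.id in (x_id, p.id, sib):
                continue
            if n.parent is None:
                self.root_id = n.id
                self.root_time = n.time
                self.root_label = n.pop
                continue
            branches.append(_Branch(n.id, n.time, g.nodes[n.parent].time,
                                    n.pop, n.events))
        s = g.nodes[sib]
        if p.parent is None:
            # sibling becomes the background root; its old branch events
            # belong to the resampled segment, not to the background
            self.root_id = sib
            self.root_time = s.time
            self.root_label = s.pop
        else:
            merged = list(s.events) + list(p.events)
            branches.append(_Branch(sib, s.time, g.nodes[p.parent].time,
                                    s.pop, merged))
        self.branches = branches
        # count-change points
        pts = []
        for b in branches:
            prev_label = b.labels[0][1]
            pts.append((b.t_start, prev_label, +1))
            for tt, lab in b.labels[1:]:
                pts.append((tt, prev_label, -1))
                pts.append((tt, lab, +1))
                prev_label = lab
            pts.append((b.t_end, prev_label, -1))
        pts.sort(key=lambda q: q[0])
        segs = []
        counts = [0] * n_pops
        t_prev = 0.0
        i = 0
        while i < len(pts):
            t = pts[i][0]
            if t > t_prev:
                segs.append((t_prev, t, tuple(counts)))
                t_prev = t
            while i < len(pts) and pts[i][0] == t:
                counts[pts[i][1]] += pts[i][2]
                i += 1
        segs.append((t_prev, math.inf, tuple(counts)))
        self.segments = segs

    def seg_index(self, t: float) -> int:
        lo, hi = 0, len(self.segments) - 1
        while lo < hi:
            mid = (lo + hi) // 2
            if self.segments[mid][1] <= t:
                lo = mid + 1
            else:
                hi = mid
        return lo

    def partners_at(self, t: float, label: int):
        return [b for b in self.branches if b.alive_at(t) and b.label_at(t) == label]


class _PathDensity:
    """Accumulates log q of a focal path against the background."""

    def __init__(self, params: ParameterSet, model: PopulationModel):
        self.params = params
        self.model = model
        self.dists = {e: DivergenceDistribution(params.div_mean[e],
                                                params.div_sd[e], params.b1)
                      for e in params.div_mean}
        self.logq = 0.0

    def exp_rate(self, label: int, k_bg: int) -> float:
        rate = k_bg * 2.0 / self.params.theta[label]
        for j in self.model.migration_sources(label):
            rate += self.params.mig.get((j, label), 0.0)
        return rate

    def survive(self, label: int, t0: float, t1: float, k_bg: int,
                pair_label: int | None = None):
        """Survival over [t0, t1]; ``pair_label`` adds the second active
        lineage's migration/divergence survival in the joint phase."""
        if t1 <= t0:
            return
        self.logq -= (t1 - t0) * self.exp_rate_pair(label, k_bg, pair_label)
        for lab in (label, pair_label):
            if lab is None:
                continue
            e = self._div_edge(lab)
            if e is not None:
                d = self.dists[e]
                self.logq -= float(d._log_sf(t0) - d._log_sf(t1))

    def exp_rate_pair(self, label, k_bg, pair_label):
        rate = self.exp_rate(label, k_bg)
        if pair_label is not None:
            # joint phase: no fixed background; coalescence only when equal
            rate = 0.0
            for j in self.model.migration_sources(label):
                rate += self.params.mig.get((j, label), 0.0)
            for j in self.model.migration_sources(pair_label):
                rate += self.params.mig.get((j, pair_label), 0.0)
            if label == pair_label:
                rate += 2.0 / self.params.theta[label]
        return rate

    def _div_edge(self, label):
        anc = self.model.ancestor_of(label)
        return (label, anc) if anc is not None else None

    def event_mig(self, frm: int, to: int):
        m = self.params.mig.get((to, frm), 0.0)
        self.logq += math.log(m) if m > 0 else -math.inf

    def event_div(self, label: int, t: float):
        e = self._div_edge(label)
        if e is None:
            self.logq = -math.inf
            return
        d = self.dists[e]
        z = (t - d.tau_mean) / d.tau_sd
        self.logq += (-0.5 * z * z - 0.5 * math.log(2 * math.pi)
                      - math.log(d.tau_sd) - float(d._log_sf(t)))

    def event_coal(self, label: int):
        self.logq += math.log(2.0 / self.params.theta[label])


def _old_path_logq(g: EventGenealogy, x_id: int, bg: _Background,
                   pd: _PathDensity) -> float:
    """Density of the existing focal segment (and, when the old parent was
    the root, the sibling's pair-phase events) under the proposal process."""
    x = g.nodes[x_id]
    p = g.nodes[x.parent]
    # timeline of the old resampled object
    moves = [("focal", ev) for ev in x.events]
    pair_start = bg.root_time
    pair_label = None
    if p.parent is None:
        sib = next(c for c in p.children if c != x_id)
        moves += [("pair", ev) for ev in g.nodes[sib].events]
        pair_label = g.nodes[sib].pop
    moves.sort(key=lambda me: me[1].time)
    t = x.time
    f = x.pop
    in_pair = t >= pair_start and pair_label is not None
    gl = pair_label if in_pair else None
    mi = 0
    while True:
        t_next_move = moves[mi][1].time if mi < len(moves) else p.time
        while True:
            # advance through background segments up to t_next_move
            if not in_pair:
                si = bg.seg_index(t)
                seg_end = min(bg.segments[si][1], pair_start
                              if pair_label is not None else math.inf)
                k_bg = bg.segments[si][2][f]
                step_end = min(seg_end, t_next_move)
                pd.survive(f, t, step_end, k_bg)
                t = step_end
                if pair_label is not None and t >= pair_start and t < t_next_move:
                    in_pair = True
                    gl = pair_label
                    continue
                if t >= t_next_move:
                    break
            else:
                pd.survive(f, t, t_next_move, 0, pair_label=gl)
                t = t_next_move
                break
        if mi >= len(moves):
            break
        who, ev = moves[mi]
        mi += 1
        if ev.kind == MIGRATION:
            pd.event_mig(ev.from_pop, ev.to_pop)
        else:
            pd.event_div(ev.from_pop, ev.time)
        if who == "focal":
            f = ev.to_pop
        else:
            gl = ev.to_pop
    # final coalescence at p.time
    if in_pair:
        if f != gl:
            return -math.inf
        pd.event_coal(f)
    else:
        pd.event_coal(f)
    return pd.logq


def propose_genealogy(g: EventGenealogy, params: ParameterSet,
                      model: PopulationModel, rng: np.random.Generator,
                      max_steps: int = 10000):
    """Detach one random lineage segment, re-simulate it, and return
    ``(proposal, log_hastings)`` where the Hastings term is
    ``log q(old | background) - log q(new | background)``.

    Returns ``None`` when the re-simulation exceeds ``max_steps`` (treated
    as a rejected proposal).
    """
    non_root = [n.id for n in g.nodes.values() if n.parent is not None]
    x_id = int(non_root[rng.integers(len(non_root))])
    bg = _Background(g, x_id, model.n_populations)
    x = g.nodes[x_id]

    pd_new = _PathDensity(params, model)
    t = x.time
    f = x.pop
    new_events: list[Event] = []
    pair_events: list[Event] = []
    gl = None  # pair-phase partner label
    in_pair = t >= bg.root_time
    if in_pair:
        gl = bg.root_label

    def draw_div(label, t_now):
        anc = model.ancestor_of(label)
        if anc is None:
            return math.inf, None
        d = pd_new.dists[(label, anc)]
        r = rng.uniform(np.finfo(float).tiny, 1.0)
        return t_now + float(sample_div_time(t_now, r, d)), anc

    t_div_f, anc_f = draw_div(f, t)
    t_div_g = math.inf
    anc_g = None
    if in_pair:
        t_div_g, anc_g = draw_div(gl, t)

    steps = 0
    partner_branch = None
    coal_time = None
    while True:
        steps += 1
        if steps > max_steps:
            return None
        if not in_pair:
            si = bg.seg_index(t)
            seg_lo, seg_hi, counts = bg.segments[si]
            seg_hi = min(seg_hi, bg.root_time)
            k_bg = counts[f]
            lam_coal = k_bg * 2.0 / params.theta[f]
            mig_pairs = [(j, params.mig.get((j, f), 0.0))
                         for j in model.migration_sources(f)]
            lam_mig = sum(m for _, m in mig_pairs)
            lam = lam_coal + lam_mig
            t_exp = t + rng.exponential(1.0 / lam) if lam > 0 else math.inf
            t_ev = min(t_exp, t_div_f)
            if t_ev < seg_hi:
                pd_new.survive(f, t, t_ev, k_bg)
                if t_ev == t_div_f:
                    new_events.append(Event(t_ev, DIVERGENCE, f, anc_f))
                    pd_new.event_div(f, t_ev)
                    f = anc_f
                    t = t_ev
                    t_div_f, anc_f = draw_div(f, t)
                else:
                    pick = rng.uniform(0, lam)
                    if pick < lam_coal:
                        partners = bg.partners_at(t_ev, f)
                        partner_branch = partners[int(rng.integers(len(partners)))]
                        pd_new.event_coal(f)
                        coal_time = t_ev
                        break
                    pick -= lam_coal
                    for j, m in mig_pairs:
                        if pick < m:
                            new_events.append(Event(t_ev, MIGRATION, f, j))
                            pd_new.event_mig(f, j)
                            f = j
                            break
                        pick -= m
                    t = t_ev
                    t_div_f, anc_f = draw_div(f, t)
            else:
                pd_new.survive(f, t, seg_hi, k_bg)
                t = seg_hi
                if t >= bg.root_time:
                    in_pair = True
                    gl = bg.root_label
                    t_div_g, anc_g = draw_div(gl, t)
        else:
            lam_coal = 2.0 / params.theta[f] if f == gl else 0.0
            mig_f = [(j, params.mig.get((j, f), 0.0))
                     for j in model.migration_sources(f)]
            mig_g = [(j, params.mig.get((j, gl), 0.0))
                     for j in model.migration_sources(gl)]
            lam_mig = sum(m for _, m in mig_f) + sum(m for _, m in mig_g)
            lam = lam_coal + lam_mig
            t_exp = t + rng.exponential(1.0 / lam) if lam > 0 else math.inf
            t_ev = min(t_exp, t_div_f, t_div_g)
            if t_ev == math.inf:
                return None
            pd_new.survive(f, t, t_ev, 0, pair_label=gl)
            if t_ev == t_div_f:
                new_events.append(Event(t_ev, DIVERGENCE, f, anc_f))
                pd_new.event_div(f, t_ev)
                f = anc_f
                t = t_ev
                t_div_f, anc_f = draw_div(f, t)
            elif t_ev == t_div_g:
                pair_events.append(Event(t_ev, DIVERGENCE, gl, anc_g))
                pd_new.event_div(gl, t_ev)
                gl = anc_g
                t = t_ev
                t_div_g, anc_g = draw_div(gl, t)
            else:
                pick = rng.uniform(0, lam)
                if pick < lam_coal:
                    pd_new.event_coal(f)
                    coal_time = t_ev
                    partner_branch = None  # background root lineage
                    break
                pick -= lam_coal
                t = t_ev
                done = False
                for j, m in mig_f:
                    if pick < m:
                        new_events.append(Event(t_ev, MIGRATION, f, j))
                        pd_new.event_mig(f, j)
                        f = j
                        t_div_f, anc_f = draw_div(f, t)
                        done = True
                        break
                    pick -= m
                if not done:
                    for j, m in mig_g:
                        if pick < m:
                            pair_events.append(Event(t_ev, MIGRATION, gl, j))
                            pd_new.event_mig(gl, j)
                            gl = j
                            t_div_g, anc_g = draw_div(gl, t)
                            break
                        pick -= m

    pd_old = _PathDensity(params, model)
    logq_old = _old_path_logq(g, x_id, bg, pd_old)

    g2 = _rebuild(g, x_id, bg, new_events, pair_events, coal_time,
                  partner_branch, f)
    return g2, logq_old - pd_new.logq


def _rebuild(g, x_id, bg, new_events, pair_events, coal_time, partner_branch,
             final_label) -> EventGenealogy:
    """Assemble the proposed genealogy from the accepted focal path."""
    g2 = g.copy()
    x = g2.nodes[x_id]
    p_id = x.parent
    p = g2.nodes[p_id]
    sib = next(c for c in p.children if c != x_id)
    # remove p, merging the sibling branch
    if p.parent is None:
        g2.nodes[sib].parent = None
        g2.nodes[sib].events = []
        g2.root = sib
    else:
        gp = g2.nodes[p.parent]
        gp.children = [sib if c == p_id else c for c in gp.children]
        g2.nodes[sib].parent = p.parent
        g2.nodes[sib].events = list(g2.nodes[sib].events) + list(p.events)
    del g2.nodes[p_id]
    new_id = p_id  # reuse the id

    x.events = new_events
    if partner_branch is not None:
        b_id = partner_branch.node_id
        b = g2.nodes[b_id]
        bp = b.parent
        below = [ev for ev in b.events if ev.time <= coal_time]
        above = [ev for ev in b.events if ev.time > coal_time]
        mid = Node(new_id, coal_time, final_label, parent=bp,
                   children=[b_id, x_id], events=above)
        g2.nodes[new_id] = mid
        if bp is not None:
            g2.nodes[bp].children = [new_id if c == b_id else c
                                     for c in g2.nodes[bp].children]
        else:
            g2.root = new_id
        b.parent = new_id
        b.events = below
        x.parent = new_id
    else:
        # coalesced with the background root lineage: new root
        r_id = g2.root
        root = g2.nodes[r_id]
        mid = Node(new_id, coal_time, final_label, parent=None,
                   children=[r_id, x_id], events=[])
        g2.nodes[new_id] = mid
        root.parent = new_id
        root.events = list(pair_events)
        x.parent = new_id
        g2.root = new_id
    return g2


def propose_event_slide(g: EventGenealogy, rng: np.random.Generator):
    """Slide one migration/divergence event uniformly within its window.

    The window is bounded by the neighbouring events on the same branch
    (or the branch ends), so the proposal is symmetric; label-switch
    events do not enter the sequence likelihood, making this move cheap
    and effective at decorrelating switch times from the divergence
    parameters.
    """
    evs = [(n.id, i) for n in g.nodes.values() if n.parent is not None
           for i in range(len(n.events))]
    if not evs:
        return None
    nid, i = evs[int(rng.integers(len(evs)))]
    n = g.nodes[nid]
    lo = n.events[i - 1].time if i > 0 else n.time
    hi = n.events[i + 1].time if i + 1 < len(n.events) else g.nodes[n.parent].time
    t_new = float(rng.uniform(lo, hi))
    g2 = g.copy()
    ev = g2.nodes[nid].events[i]
    g2.nodes[nid].events[i] = Event(t_new, ev.kind, ev.from_pop, ev.to_pop)
    return g2, 0.0


def propose_node_slide(g: EventGenealogy, rng: np.random.Generator):
    """Slide one non-root coalescence time uniformly within its window.

    The window respects the events on the three adjacent branches, so the
    move is symmetric; topology and labels are unchanged.
    """
    internal = [n.id for n in g.nodes.values()
                if n.children and n.parent is not None]
    if not internal:
        return None
    nid = int(internal[rng.integers(len(internal))])
    n = g.nodes[nid]
    lo = 0.0
    for c in n.children:
        cn = g.nodes[c]
        lo = max(lo, cn.events[-1].time if cn.events else cn.time)
    hi = n.events[0].time if n.events else g.nodes[n.parent].time
    if hi <= lo:
        return None
    t_new = float(rng.uniform(lo, hi))
    g2 = g.copy()
    g2.nodes[nid].time = t_new
    return g2, 0.0



def _shift_divergence_events(gs, edge, delta, model):
    """Translate every divergence event on ``edge`` by ``delta`` in all
    loci; returns the shifted genealogies or None if any event would leave
    its branch or break the label sequence."""
    out = []
    for g in gs:
        g2 = g.copy()
        changed = False
        for n in g2.nodes.values():
            if not n.events or n.parent is None:
                continue
            moved = False
            evs = []
            for ev in n.events:
                if ev.kind == DIVERGENCE and (ev.from_pop, ev.to_pop) == edge:
                    evs.append(Event(ev.time + delta, ev.kind, ev.from_pop,
                                     ev.to_pop))
                    moved = True
                else:
                    evs.append(ev)
            if moved:
                evs.sort(key=lambda e: e.time)
                lo = n.time
                hi = g2.nodes[n.parent].time
                if evs[0].time <= lo or evs[-1].time >= hi:
                    return None
                cur = n.pop
                for ev in evs:
                    if ev.from_pop != cur:
                        return None
                    cur = ev.to_pop
                n.events = evs
                changed = True
        out.append(g2 if changed else g)
    return out


# ---------------------------------------------------------------------------
# starting genealogies
# ---------------------------------------------------------------------------

def population_map_from_names(model: PopulationModel, names) -> dict:
    """Infer tip -> population from names like '<poplabel>_<k>'."""
    out = {}
    for nm in names:
        stem = nm.rsplit("_", 1)[0]
        out[nm] = model.index(stem)
    return out


def initial_genealogy(aln: dict | None, model: PopulationModel,
                      params: ParameterSet, rng: np.random.Generator,
                      pop_of: dict | None = None) -> EventGenealogy:
    """Build a valid starting genealogy.

    With data: UPGMA on Jukes-Cantor distances (an ultrametric tree close
    to the data) followed by a label-repair pass that inserts the
    divergence/migration events needed to make every coalescence join
    identically-labelled lineages.  Without data: simulate from the model.
    """
    if aln is None:
        from popsplit.simulate import SimulationConfig, simulate_genealogy
        cfg = SimulationConfig(model, params, seed=0)
        return simulate_genealogy(cfg, rng)
    names, arr = encode_alignment(aln)
    pop_of = pop_of or population_map_from_names(model, names)
    n = len(names)
    codes = arr.argmax(axis=2)
    informative = arr.sum(axis=2) == 1
    dist = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            ok = informative[i] & informative[j]
            p_mis = float(np.mean(codes[i][ok] != codes[j][ok])) if ok.any() else 0.0
            p_mis = min(p_mis, 0.70)
            d = -0.75 * math.log1p(-4.0 * p_mis / 3.0)
            dist[i, j] = dist[j, i] = d
    iu = np.triu_indices(n, 1)
    z = linkage(dist[iu], method="average")
    nodes = {}
    for i, nm in enumerate(names):
        nodes[i] = Node(i, 0.0, pop_of[nm], name=nm)
    floor = 0.0
    for row_i, (a, b, h, _) in enumerate(z):
        t = max(h / 2.0, floor * (1 + 1e-9) + 1e-9)
        floor = t
        nid = n + row_i
        nodes[nid] = Node(nid, t, 0, children=[int(a), int(b)])
        nodes[int(a)].parent = nid
        nodes[int(b)].parent = nid
    g = EventGenealogy(nodes, 2 * n - 2)
    _repair_labels(g, model, rng)
    issues = g.validate(model)
    if issues:
        raise RuntimeError("label repair failed: " + "; ".join(issues))
    return g


def _div_chain(model: PopulationModel, label: int) -> list[int]:
    chain = [label]
    cur = label
    seen = {label}
    while True:
        anc = model.ancestor_of(cur)
        if anc is None or anc in seen:
            return chain
        chain.append(anc)
        seen.add(anc)
        cur = anc


def _repair_labels(g: EventGenealogy, model: PopulationModel,
                   rng: np.random.Generator):
    """Insert events so each coalescence joins equal labels (postorder)."""
    order = []
    stack = [(g.root, False)]
    while stack:
        nid, done = stack.pop()
        node = g.nodes[nid]
        if done or not node.children:
            order.append(nid)
            continue
        stack.append((nid, True))
        for c in node.children:
            stack.append((c, False))
    for nid in order:
        node = g.nodes[nid]
        if not node.children:
            continue
        a, b = node.children
        la = g.branch_end_label(a)
        lb = g.branch_end_label(b)
        if la == lb:
            node.pop = la
            continue
        ca, cb = _div_chain(model, la), _div_chain(model, lb)
        target = next((x for x in ca if x in cb), None)
        if target is None:
            # no common divergence ancestor: migrate one lineage across
            if (la, lb) in model.migration_edges:
                _insert_moves(g, b, [la], node.time, MIGRATION)
                node.pop = la
                continue
            if (lb, la) in model.migration_edges:
                _insert_moves(g, a, [lb], node.time, MIGRATION)
                node.pop = lb
                continue
            raise RuntimeError(
                f"cannot reconcile labels {la} and {lb}: populations unconnected")
        _insert_moves(g, a, ca[1:ca.index(target) + 1], node.time, DIVERGENCE)
        _insert_moves(g, b, cb[1:cb.index(target) + 1], node.time, DIVERGENCE)
        node.pop = target


def _insert_moves(g: EventGenealogy, child_id: int, path: list[int],
                  t_top: float, kind: str):
    node = g.nodes[child_id]
    t_lo = node.events[-1].time if node.events else node.time
    cur = g.branch_end_label(child_id)
    k = len(path)
    for step, nxt in enumerate(path):
        frac = (step + 1) / (k + 1)
        t_ev = t_lo + (t_top - t_lo) * frac
        node.events.append(Event(t_ev, kind, cur, nxt))
        cur = nxt


# ---------------------------------------------------------------------------
# the chain
# ---------------------------------------------------------------------------

def summarize_posterior(samples, name: str = "param", bins: int = 1500,
                        support: tuple[float, float] | None = None) -> PosteriorSummary:
    """Histogram summary: smoothed-mode, percentiles, standardised width.

    The mode is the midpoint of the highest histogram bin after a 3-bin
    moving average; the standardised credibility width is
    (p97.5 - p2.5) / mode.  Needs >= 100 samples; constant samples are
    flagged degenerate with width 0.
    """
    x = np.asarray(samples, dtype=float)
    if x.size < 100:
        raise ValueError("need at least 100 retained samples")
    if np.ptp(x) == 0:
        c = float(x[0])
        return PosteriorSummary(name, c, c, c, 0.0, c, float("nan"),
                                np.array([1.0]), np.array([c, c]),
                                degenerate=True)
    lo, hi = support if support is not None else (float(x.min()), float(x.max()))
    hist, edges = np.histogram(x, bins=bins, range=(lo, hi), density=True)
    smooth = np.convolve(hist, np.ones(3) / 3.0, mode="same")
    mode = float(0.5 * (edges[np.argmax(smooth)] + edges[np.argmax(smooth) + 1]))
    p2_5, p97_5 = np.percentile(x, [2.5, 97.5])
    width = (p97_5 - p2_5) / mode if mode > 0 else math.inf
    return PosteriorSummary(name, mode, float(p2_5), float(p97_5),
                            float(width), float(x.mean()), _ess(x), hist, edges)


def _ess(x: np.ndarray, max_lag: int | None = None) -> float:
    """Effective sample size by the initial positive-sequence estimator."""
    n = len(x)
    xc = x - x.mean()
    var = float(np.dot(xc, xc)) / n
    if var == 0:
        return float(n)
    max_lag = max_lag or min(n // 3, 1000)
    rho_sum = 0.0
    for lag in range(1, max_lag):
        rho = float(np.dot(xc[:-lag], xc[lag:])) / ((n - lag) * var)
        if rho < 0.05:
            break
        rho_sum += rho
    return n / (1.0 + 2.0 * rho_sum)


def run_chain(data, model: PopulationModel, priors: dict, chain: ChainConfig,
              mutation: MutationModel | None = None,
              initial_params: ParameterSet | None = None,
              pop_of: dict | None = None, b1: float = math.inf) -> ChainResult:
    """Sample the posterior of all model parameters.

    ``data`` is a list of per-locus alignments (tip name -> sequence) or
    ``None`` for a prior-only run (the sequence term is dropped, which
    must recover the priors — a standard sampler validity check).
    """
    rng = np.random.default_rng(chain.seed)
    entries = _param_entries(model)
    mutation = mutation or MutationModel()
    div_edges = sorted(model.divergence_edges)
    mig_edges = sorted(model.migration_edges)

    # initial parameters: prior draws unless given
    if initial_params is None:
        vals = {(\
            kind, key): priors[name].sample(rng) for name, kind, key in entries}
        initial_params = ParameterSet(
            theta=tuple(vals[("theta", i)] for i in range(model.n_populations)),
            mig={e: vals[("mig", e)] for e in mig_edges},
            div_mean={e: vals[("div_mean", e)] for e in div_edges},
            div_sd={e: vals[("div_sd", e)] for e in div_edges},
            b1=b1)
    params = initial_params

    n_loci = len(data) if data is not None else 1
    comp = ([a if isinstance(a, CompressedAlignment) else CompressedAlignment(a)
             for a in data] if data is not None else None)
    gs, stats, logls = [], [], []
    for l in range(n_loci):
        aln = data[l] if data is not None else None
        g = initial_genealogy(aln, model, params, rng, pop_of=pop_of)
        gs.append(g)
        stats.append(_GenealogyStats(g, model, div_edges, mig_edges))
        logls.append(pruning_loglike(g, comp[l], mutation) if aln is not None else 0.0)

    def log_prior(p):
        tot = 0.0
        for name, kind, key in entries:
            tot += priors[name].logpdf(_get_param(p, kind, key))
        return tot

    logf = [s.log_density(params) for s in stats]
    lp = log_prior(params)
    if not np.isfinite(lp + sum(logf)):
        raise RuntimeError("invalid starting state (zero prior or density)")

    windows = {name: 0.3 * (priors[name].upper - priors[name].lower)
               for name, _, _ in entries}
    # the joint tau+switch-time translation gets its own (separately
    # tuned) step size: its acceptance profile differs from the plain move
    for name, kind, _ in entries:
        if kind == "div_mean":
            windows[name + "+shift"] = 0.05 * (priors[name].upper - priors[name].lower)
    acc = {name: [0, 0] for name in windows}
    acc["genealogy"] = [0, 0]

    kept = []
    lp_trace = []
    n_params = len(entries)
    acc["node_slide"] = [0, 0]
    acc["event_slide"] = [0, 0]
    for it in range(chain.length):
        u_move = rng.uniform()
        if u_move < chain.genealogy_weight:
            # split tree updates between path re-simulation and the two
            # symmetric within-topology time slides
            frac = u_move / chain.genealogy_weight
            l = int(rng.integers(n_loci))
            if frac < 0.4:
                kind = "genealogy"
                prop = propose_genealogy(gs[l], params, model, rng)
                likelihood_changes = True
            elif frac < 0.7:
                kind = "node_slide"
                prop = propose_node_slide(gs[l], rng)
                likelihood_changes = True
            else:
                kind = "event_slide"
                prop = propose_event_slide(gs[l], rng)
                likelihood_changes = False
            acc[kind][1] += 1
            if prop is not None:
                g2, log_h = prop
                st2 = _GenealogyStats(g2, model, div_edges, mig_edges)
                lf2 = st2.log_density(params)
                if likelihood_changes and data is not None:
                    ll2 = pruning_loglike(g2, comp[l], mutation)
                else:
                    ll2 = logls[l]
                delta = (lf2 + ll2) - (logf[l] + logls[l]) + log_h
                if delta >= 0 or rng.uniform() < math.exp(max(delta, -700)):
                    gs[l], stats[l], logf[l], logls[l] = g2, st2, lf2, ll2
                    acc[kind][0] += 1
        else:
            name, kind, key = entries[int(rng.integers(n_params))]
            pr = priors[name]
            cur = _get_param(params, kind, key)
            joint_shift = kind == "div_mean" and rng.uniform() < 0.5
            wname = name + "+shift" if joint_shift else name
            w = windows[wname]
            newv = cur + w * (rng.uniform() - 0.5)
            # reflect at the prior bounds
            span = pr.upper - pr.lower
            while newv < pr.lower or newv > pr.upper:
                if newv < pr.lower:
                    newv = 2 * pr.lower - newv
                if newv > pr.upper:
                    newv = 2 * pr.upper - newv
            try:
                p2 = _set_param(params, kind, key, newv)
            except ValueError:
                p2 = None
            acc[wname][1] += 1
            if p2 is not None and joint_shift:
                # translate the divergence mean together with every switch
                # time of this edge: breaks the stiff tau/event coupling
                gs2 = _shift_divergence_events(gs, key, newv - cur, model)
                if gs2 is None:
                    p2 = None
                else:
                    st_new = [_GenealogyStats(g2, model, div_edges, mig_edges)
                              for g2 in gs2]
                    lf2 = [st.log_density(p2) for st in st_new]
                    delta = (log_prior(p2) + sum(lf2)) - (log_prior(params) + sum(logf))
                    if np.isfinite(delta) and (
                            delta >= 0 or rng.uniform() < math.exp(max(delta, -700))):
                        params, gs, stats, logf = p2, gs2, st_new, lf2
                        acc[wname][0] += 1
                    p2 = None  # handled
            if p2 is not None:
                lf2 = [s.log_density(p2) for s in stats]
                delta = (log_prior(p2) + sum(lf2)) - (log_prior(params) + sum(logf))
                if np.isfinite(delta) and (
                        delta >= 0 or rng.uniform() < math.exp(max(delta, -700))):
                    params = p2
                    logf = lf2
                    acc[wname][0] += 1
            # tune during burn-in
            if it < chain.burnin and acc[wname][1] % 50 == 0:
                rate = acc[wname][0] / acc[wname][1]
                if rate > 0.4:
                    windows[wname] = min(w * 1.4, span)
                elif rate < 0.2:
                    windows[wname] = w / 1.4
        if it >= chain.burnin and (it - chain.burnin) % chain.thin == 0:
            kept.append([_get_param(params, kind, key)
                         for _, kind, key in entries])
            lp_trace.append(log_prior(params) + sum(logf) + sum(logls))

    samples = np.array(kept)
    names = [name for name, _, _ in entries]
    summaries = {}
    for i, name in enumerate(names):
        pr = priors[name]
        summaries[name] = summarize_posterior(
            samples[:, i], name=name, bins=chain.bins,
            support=(pr.lower, pr.upper))
    rates = {k: (v[0] / v[1] if v[1] else float("nan")) for k, v in acc.items()}
    return ChainResult(summaries, samples, names, rates, chain.seed,
                       np.array(lp_trace))
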