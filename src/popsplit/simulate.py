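"""Backward-in-time simulation of event-augmented genealogies and sequences.

For every interval the simulator proposes a waiting time for each possible
event independently — exponential draws for coalescence and migration,
survival-function inversion for the truncated-normal divergence hazard —
and applies the event that comes first.  This competing-draws scheme
produces events at exactly the frequencies of the xi probabilities without
evaluating them.

Two divergence modes are supported: ``per-lineage-hazard`` (the inference
model: every derived lineage draws its own switching time) and
``shared-epoch`` (one zero-truncated normal epoch per dataset, then a hard
split — the convention of classic divergence simulators).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from popsplit.genealogy import DIVERGENCE, MIGRATION, Event, EventGenealogy, Node
from popsplit.hazards import DivergenceDistribution, sample_div_time
from popsplit.likelihood import BASES, MutationModel, f84_transition_matrix
from popsplit.popmodel import ParameterSet, PopulationModel

__all__ = [
    "SimulationConfig",
    "simulate_genealogy",
    "simulate_dataset",
    "simulate_sequences",
    "lineage_survival_fraction",
    "draw_divergence_epoch",
]

PER_LINEAGE = "per-lineage-hazard"
SHARED_EPOCH = "shared-epoch"


@dataclass(frozen=True)
class SimulationConfig:
    """Settings for a multi-locus simulated dataset."""

    model: PopulationModel
    params: ParameterSet
    loci: int = 1
    sites: int = 1000
    seed: int = 0
    div_mode: str = PER_LINEAGE
    mutation: MutationModel = field(default_factory=MutationModel)

    def __post_init__(self):
        if self.loci < 1 or self.sites < 1:
            raise ValueError("loci and sites must be >= 1")
        if self.div_mode not in (PER_LINEAGE, SHARED_EPOCH):
            raise ValueError(f"unknown divergence mode {self.div_mode!r}")


def draw_divergence_epoch(tau_mean: float, tau_sd: float,
                          rng: np.random.Generator) -> float:
    """One shared divergence epoch: a normal draw, redrawn while <= 0.

    Rejection at zero implements the zero truncation; with ``tau_sd = 0``
    the epoch is exactly ``tau_mean``.
    """
    if tau_sd < 0:
        raise ValueError("tau_sd must be >= 0")
    if tau_sd == 0:
        return tau_mean
    while True:
        t = rng.normal(tau_mean, tau_sd)
        if t > 0:
            return t


def _tip_nodes(model: PopulationModel) -> dict[int, Node]:
    nodes: dict[int, Node] = {}
    nid = 0
    for pop, count in enumerate(model.sample_counts):
        for k in range(count):
            nodes[nid] = Node(nid, 0.0, pop, name=f"{model.population_labels[pop]}_{k}")
            nid += 1
    return nodes


def simulate_genealogy(config: SimulationConfig,
                       rng: np.random.Generator | None = None,
                       locus: str | None = None,
                       max_events: int = 1_000_000) -> EventGenealogy:
    """Simulate one event-augmented genealogy under the model.

    Competing candidate times per interval: one exponential per population
    with >= 2 lineages (coalescence), one exponential per immigration edge
    (total rate ``k_i M_ji``), and one inverse-transform draw per
    divergence edge from the pooled ``k``-lineage hazard.  The earliest
    candidate is applied; the loop ends at the most recent common
    ancestor.  ``max_events`` guards against models whose lineages can
    never merge (e.g. disconnected populations).
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    model, params = config.model, config.params
    nodes = _tip_nodes(model)
    next_id = len(nodes)
    active: dict[int, list[int]] = {i: [] for i in range(model.n_populations)}
    for n in nodes.values():
        active[n.pop].append(n.id)

    dists = {edge: DivergenceDistribution(params.div_mean[edge],
                                          params.div_sd[edge], params.b1)
             for edge in params.div_mean}
    epochs: dict[tuple[int, int], float] = {}
    if config.div_mode == SHARED_EPOCH:
        epochs = {edge: draw_divergence_epoch(params.div_mean[edge],
                                              params.div_sd[edge], rng)
                  for edge in params.div_mean}

    t = 0.0
    n_events = 0
    while sum(len(v) for v in active.values()) > 1:
        candidates: list[tuple[float, tuple]] = []
        for pop in range(model.n_populations):
            k = len(active[pop])
            if k >= 2:
                rate = k * (k - 1) / params.theta[pop]
                candidates.append((t + rng.exponential(1.0 / rate), ("coal", pop)))
        for (j, i), m in params.mig.items():
            k = len(active[i])
            if k >= 1 and m > 0:
                candidates.append((t + rng.exponential(1.0 / (k * m)), ("mig", j, i)))
        for edge, dist in dists.items():
            der, anc = edge
            k = len(active[der])
            if k < 1:
                continue
            if config.div_mode == SHARED_EPOCH:
                if t < epochs[edge]:
                    candidates.append((epochs[edge], ("div", der, anc)))
                else:  # past the epoch: switch immediately
                    candidates.append((t * (1 + 1e-12) + 1e-300, ("div", der, anc)))
            else:
                # min of k iid hazard draws == one draw from the k-fold hazard
                r = rng.uniform(np.finfo(float).tiny, 1.0)
                r_pooled = -math.expm1(math.log1p(-r) / k)
                u = float(sample_div_time(t, r_pooled, dists[edge]))
                candidates.append((t + max(u, 1e-300), ("div", der, anc)))
        if not candidates:
            raise RuntimeError("no feasible events: populations cannot merge under this model")
        t_ev, what = min(candidates, key=lambda c: c[0])
        t = t_ev
        n_events += 1
        if n_events > max_events:
            raise RuntimeError(f"runaway simulation: more than {max_events} events")

        if what[0] == "coal":
            pop = what[1]
            pair = rng.choice(len(active[pop]), size=2, replace=False)
            a, b = (active[pop][int(pair[0])], active[pop][int(pair[1])])
            parent = Node(next_id, t, pop, children=[a, b])
            nodes[next_id] = parent
            nodes[a].parent = next_id
            nodes[b].parent = next_id
            active[pop] = [x for x in active[pop] if x not in (a, b)]
            active[pop].append(next_id)
            next_id += 1
        elif what[0] == "mig":
            j, i = what[1], what[2]
            idx = int(rng.integers(len(active[i])))
            lin = active[i].pop(idx)
            nodes[lin].events.append(Event(t, MIGRATION, i, j))
            active[j].append(lin)
        else:
            der, anc = what[1], what[2]
            idx = int(rng.integers(len(active[der])))
            lin = active[der].pop(idx)
            nodes[lin].events.append(Event(t, DIVERGENCE, der, anc))
            active[anc].append(lin)

    root = next(x for v in active.values() for x in v)
    return EventGenealogy(nodes, root, locus)


def simulate_sequences(g: EventGenealogy, sites: int, mutation: MutationModel,
                       rng: np.random.Generator) -> dict[str, str]:
    """Evolve sequences down the genealogy under F84.

    The root state is drawn from the stationary base frequencies; each
    branch applies its F84 transition matrix.  Returns tip name -> sequence.
    """
    pi = np.asarray(mutation.freqs)
    states: dict[int, np.ndarray] = {
        g.root: rng.choice(4, size=sites, p=pi)
    }
    out: dict[str, str] = {}
    stack = [g.root]
    while stack:
        nid = stack.pop()
        node = g.nodes[nid]
        state = states.pop(nid)
        if not node.children:
            out[node.name] = "".join(BASES[s] for s in state)
            continue
        for c in node.children:
            t = node.time - g.nodes[c].time
            p = f84_transition_matrix(t, mutation)
            cum = np.cumsum(p, axis=1)
            u = rng.random(sites)
            child_state = (u[:, None] > cum[state]).sum(axis=1)
            states[c] = child_state
            stack.append(c)
    return out


def simulate_dataset(config: SimulationConfig):
    """Simulate ``config.loci`` independent loci.

    Returns ``(genealogies, alignments)``; per-locus RNG streams are
    spawned from the single seed so loci are independent and reproducible.
    """
    ss = np.random.SeedSequence(config.seed)
    genealogies, alignments = [], []
    for locus, child in enumerate(ss.spawn(config.loci)):
        rng = np.random.default_rng(child)
        g = simulate_genealogy(config, rng, locus=f"locus{locus}")
        genealogies.append(g)
        alignments.append(simulate_sequences(g, config.sites, config.mutation, rng))
    return genealogies, alignments


def lineage_survival_fraction(config: SimulationConfig, tau_grid,
                              reps: int = 1000,
                              rng: np.random.Generator | None = None) -> np.ndarray:
    """Fraction of replicates with >= 2 uncoalesced lineages at each tau.

    Simulates the structured coalescent with migration (the phase of the
    isolation-with-migration model below the split) and records the time
    to the most recent common ancestor; the survival fraction at ``tau``
    is the fraction of replicates whose TMRCA exceeds ``tau``.  A fast
    count-based (lineage-number) simulation is used: lineage identities do
    not affect the coalescence and migration rates.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    tau_grid = np.asarray(tau_grid, dtype=float)
    model, params = config.model, config.params
    n = model.n_populations
    tmrca = np.empty(reps)
    tau_max = float(tau_grid.max())
    for r in range(reps):
        counts = list(model.sample_counts)
        t = 0.0
        while sum(counts) > 1:
            rates, labels = [], []
            for i in range(n):
                k = counts[i]
                if k >= 2:
                    rates.append(k * (k - 1) / params.theta[i])
                    labels.append(("coal", i))
            for (j, i), m in params.mig.items():
                if counts[i] >= 1 and m > 0:
                    rates.append(counts[i] * m)
                    labels.append(("mig", j, i))
            total = sum(rates)
            if total == 0:
                raise RuntimeError("no feasible events before the split")
            t += rng.exponential(1.0 / total)
            if t > tau_max:
                break
            pick = rng.random() * total
            acc = 0.0
            for rate, lab in zip(rates, labels):
                acc += rate
                if pick <= acc:
                    if lab[0] == "coal":
                        counts[lab[1]] -= 1
                    else:
                        counts[lab[2]] -= 1
                        counts[lab[1]] += 1
                    break
        tmrca[r] = t if sum(counts) == 1 else math.inf
    return np.array([(tmrca > tau).mean() for tau in tau_grid])
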