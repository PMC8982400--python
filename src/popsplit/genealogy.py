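"""Event-augmented coalescent genealogies and their probability density.

A genealogy is an ultrametric binary tree (tips at time 0, node times
increasing into the past) whose branches carry time-stamped migration and
divergence (label-switch) events.  Its density given the model parameters
is a product over the time intervals bounded by every tip, event and
coalescence time: each interval contributes the survival of all competing
risks (coalescence and migration as constant rates, divergence through the
per-edge cumulative hazard multiplied by the number of at-risk derived
lineages) and the rate of the event terminating it — ``2/Theta_i`` for the
observed coalescing pair, ``M_ji`` for a migration, the switching
lineage's hazard ``lambda_d(t)`` for a divergence.  Everything is accumulated
in log space; products over a thousand loci would otherwise underflow.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field

import numpy as np

from popsplit.hazards import DivergenceDistribution, div_cum_hazard, div_log_hazard
from popsplit.popmodel import ParameterSet, PopulationModel

__all__ = [
    "Event",
    "Node",
    "EventGenealogy",
    "IntervalState",
    "coalescent_rate",
    "migration_total_rate",
    "interval_log_density",
    "genealogy_log_density",
    "to_newick",
    "from_newick",
]

MIGRATION = "migration"
DIVERGENCE = "divergence"


@dataclass(frozen=True)
class Event:
    """A label switch on a branch: at ``time`` the lineage moves
    ``from_pop -> to_pop`` (backward in time)."""

    time: float
    kind: str  # MIGRATION or DIVERGENCE
    from_pop: int
    to_pop: int


@dataclass
class Node:
    id: int
    time: float
    pop: int                      # lineage label just above this node
    parent: int | None = None
    children: list[int] = field(default_factory=list)
    name: str | None = None
    events: list[Event] = field(default_factory=list)  # on branch to parent, ascending


class EventGenealogy:
    """Ultrametric binary tree with migration/divergence events on branches."""

    def __init__(self, nodes: dict[int, Node], root: int, locus: str | None = None):
        self.nodes = nodes
        self.root = root
        self.locus = locus

    # -- basic structure -------------------------------------------------
    def tips(self) -> list[Node]:
        return [n for n in self.nodes.values() if not n.children]

    @property
    def n_tips(self) -> int:
        return sum(1 for n in self.nodes.values() if not n.children)

    def copy(self) -> "EventGenealogy":
        nodes = {
            i: Node(n.id, n.time, n.pop, n.parent, list(n.children), n.name,
                    list(n.events))
            for i, n in self.nodes.items()
        }
        return EventGenealogy(nodes, self.root, self.locus)

    def label_at(self, node_id: int, t: float) -> int:
        """Population label of the branch above ``node_id`` at time ``t``."""
        n = self.nodes[node_id]
        pop = n.pop
        for ev in n.events:
            if ev.time <= t:
                pop = ev.to_pop
            else:
                break
        return pop

    def branch_end_label(self, node_id: int) -> int:
        n = self.nodes[node_id]
        return n.events[-1].to_pop if n.events else n.pop

    # -- validation ------------------------------------------------------
    def validate(self, model: PopulationModel | None = None) -> list[str]:
        """Return all invariant violations (empty for a valid genealogy)."""
        issues: list[str] = []
        tips = self.tips()
        if any(abs(t.time) > 1e-12 for t in tips):
            issues.append("tips must sit at time 0 (ultrametric tree)")
        for n in self.nodes.values():
            if n.children and len(n.children) != 2:
                issues.append(f"node {n.id} is not binary")
            if n.parent is not None:
                p = self.nodes[n.parent]
                if p.time <= n.time:
                    issues.append(f"node {n.id} is not younger than its parent")
                times = [ev.time for ev in n.events]
                if times != sorted(times):
                    issues.append(f"events on branch above node {n.id} are unordered")
                if times and (times[0] <= n.time or times[-1] >= p.time):
                    issues.append(f"events on branch above node {n.id} leave the branch")
                cur = n.pop
                for ev in n.events:
                    if ev.from_pop != cur:
                        issues.append(
                            f"event on branch above node {n.id} starts from label "
                            f"{ev.from_pop}, lineage carries {cur}")
                    if model is not None:
                        if ev.kind == MIGRATION and (ev.to_pop, ev.from_pop) not in model.migration_edges:
                            issues.append(
                                f"migration event {ev.from_pop}->{ev.to_pop} uses an undeclared edge")
                        if ev.kind == DIVERGENCE and (ev.from_pop, ev.to_pop) not in model.divergence_edges:
                            issues.append(
                                f"divergence event {ev.from_pop}->{ev.to_pop} uses an undeclared edge")
                    cur = ev.to_pop
            if len(n.children) == 2:
                for c in n.children:
                    if self.branch_end_label(c) != n.pop:
                        issues.append(
                            f"coalescence at node {n.id} joins lineages with "
                            f"inconsistent labels")
        return issues


@dataclass(frozen=True)
class IntervalState:
    """One time slice of the genealogy with its terminating event.

    ``counts[i]`` is the number of lineages carrying label ``i`` during the
    interval ``[t0, t0 + u]``; ``event`` is ``('coalescence', pop)``,
    ``('migration', from_pop, to_pop)``, ``('divergence', from_pop, to_pop)``
    or ``None`` for a slice terminated by another lineage's boundary.
    """

    t0: float
    u: float
    counts: tuple[int, ...]
    event: tuple | None


def coalescent_rate(k: int, theta: float) -> float:
    """Total pairwise coalescence rate ``k (k-1) / Theta`` in one population."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    if k < 0:
        raise ValueError("lineage count must be non-negative")
    return k * (k - 1) / theta


def migration_total_rate(counts, params: ParameterSet, model: PopulationModel) -> float:
    """Total immigration rate ``sum_i sum_j k_i M_ji`` over all edges."""
    total = 0.0
    for (j, i), m in params.mig.items():
        total += counts[i] * m
    return total


def _divergence_distributions(params: ParameterSet) -> dict[tuple[int, int], DivergenceDistribution]:
    return {
        edge: DivergenceDistribution(params.div_mean[edge], params.div_sd[edge], params.b1)
        for edge in params.div_mean
    }


def interval_log_density(state: IntervalState, params: ParameterSet,
                         model: PopulationModel,
                         _dists: dict | None = None) -> float:
    """Log density contribution of one time slice of the genealogy.

    Survival term: ``-u * (lam_c + lam_m) - sum_edges k_derived * Lambda_d``;
    event term: ``log 2/Theta_i``, ``log M_ji`` or ``log lambda_d(t)``.
    Returns ``-inf`` for an event whose rate is zero in the current state.
    """
    counts = state.counts
    dists = _dists if _dists is not None else _divergence_distributions(params)
    lam_c = sum(coalescent_rate(k, th) for k, th in zip(counts, params.theta))
    lam_m = migration_total_rate(counts, params, model)
    log_p = -state.u * (lam_c + lam_m)
    for (der, anc), dist in dists.items():
        k = counts[der]
        if k > 0:
            log_p -= k * float(div_cum_hazard(state.t0, state.u, dist))

    ev = state.event
    if ev is None:
        return log_p
    t_end = state.t0 + state.u
    if ev[0] == "coalescence":
        pop = ev[1]
        if counts[pop] < 2:
            return -math.inf
        log_p += math.log(2.0 / params.theta[pop])
    elif ev[0] == "migration":
        frm, to = ev[1], ev[2]
        m = params.mig.get((to, frm), 0.0)
        if counts[frm] < 1 or m <= 0:
            return -math.inf
        log_p += math.log(m)
    elif ev[0] == "divergence":
        frm, to = ev[1], ev[2]
        dist = dists.get((frm, to))
        k = counts[frm]
        if dist is None or k < 1:
            return -math.inf
        # per-lineage hazard: the genealogy records which lineage switched,
        # so the k at-risk lineages appear in the exponent, not the factor
        log_p += float(div_log_hazard(t_end, dist))
    else:
        raise ValueError(f"unknown event kind {ev[0]!r}")
    return log_p


def iter_interval_states(g: EventGenealogy, model: PopulationModel):
    """Decompose ``g`` into :class:`IntervalState` slices, tips to root.

    A breakpoint is placed at every event and node time on any lineage, so
    each slice has constant lineage counts per population.
    """
    boundaries: list[tuple[float, int, tuple]] = []  # (time, order, payload)
    for n in g.nodes.values():
        if len(n.children) == 2:
            boundaries.append((n.time, n.id, ("coalescence", n.pop, n.id)))
        for ev in n.events:
            kind = "migration" if ev.kind == MIGRATION else "divergence"
            boundaries.append((ev.time, n.id, (kind, ev.from_pop, ev.to_pop)))
    boundaries.sort(key=lambda b: (b[0], b[1]))

    counts = [0] * model.n_populations
    for tip in g.tips():
        counts[tip.pop] += 1
    t_cur = 0.0
    for t, _, payload in boundaries:
        if payload[0] == "coalescence":
            pop = payload[1]
            event = ("coalescence", pop)
        else:
            event = payload
        yield IntervalState(t_cur, t - t_cur, tuple(counts), event)
        if event[0] == "coalescence":
            counts[event[1]] -= 1
        else:
            counts[event[1]] -= 1
            counts[event[2]] += 1
        t_cur = t


def genealogy_log_density(g: EventGenealogy, params: ParameterSet,
                          model: PopulationModel) -> float:
    """Log density f(G | rho) of an event-augmented genealogy.

    Raises ``ValueError`` listing the violations when ``g`` is invalid.
    """
    issues = g.validate(model)
    if issues:
        raise ValueError("invalid genealogy: " + "; ".join(issues))
    dists = _divergence_distributions(params)
    total = 0.0
    for state in iter_interval_states(g, model):
        total += interval_log_density(state, params, model, _dists=dists)
        if total == -math.inf:
            break
    return total


# -- event-annotated Newick ----------------------------------------------
# Branch annotation dialect: every node carries a bracket comment
#   [&pop=<label-index-1-based>,events=<kind>:<time>:<from>><to>|...]
# where kind is 'm' or 'd'; times are absolute (not branch-relative).

_TOKEN = re.compile(r"\s*([(),;]|[^(),;\[\]:]+(?:\[[^\]]*\])?(?::[0-9.eE+-]+)?)")


def to_newick(g: EventGenealogy) -> str:
    def annot(n: Node) -> str:
        parts = [f"pop={n.pop + 1}"]
        if n.events:
            evs = "|".join(
                f"{'m' if e.kind == MIGRATION else 'd'}:{e.time:.12g}:"
                f"{e.from_pop + 1}>{e.to_pop + 1}"
                for e in n.events)
            parts.append(f"events={evs}")
        return "[&" + ",".join(parts) + "]"

    def render(nid: int) -> str:
        n = g.nodes[nid]
        if n.children:
            inner = ",".join(render(c) for c in n.children)
            label = f"({inner})"
        else:
            label = n.name or f"t{n.id}"
        blen = ""
        if n.parent is not None:
            blen = f":{g.nodes[n.parent].time - n.time:.12g}"
        return label + annot(n) + blen

    return render(g.root) + ";"


def from_newick(text: str, locus: str | None = None) -> EventGenealogy:
    text = text.strip().rstrip(";")
    pos = 0
    nodes: dict[int, Node] = {}
    next_id = [0]

    def new_node() -> Node:
        n = Node(next_id[0], 0.0, 0)
        next_id[0] += 1
        nodes[n.id] = n
        return n

    def parse_annot(n: Node, payload: str):
        body = payload.strip()[1:-1]
        if body.startswith("&"):
            body = body[1:]
        for part in body.split(","):
            key, _, val = part.partition("=")
            if key == "pop":
                n.pop = int(val) - 1
            elif key == "events":
                for ev in val.split("|"):
                    kind, t, move = ev.split(":")
                    frm, to = move.split(">")
                    n.events.append(Event(
                        float(t),
                        MIGRATION if kind == "m" else DIVERGENCE,
                        int(frm) - 1, int(to) - 1))

    def parse(parent_time_holder) -> tuple[Node, float]:
        """Returns (node, branch_length)."""
        nonlocal pos
        n = new_node()
        if text[pos] == "(":
            pos += 1
            child, bl = parse(None)
            n.children.append(child.id)
            child.parent = n.id
            child_blens = [bl]
            while text[pos] == ",":
                pos += 1
                child, bl = parse(None)
                n.children.append(child.id)
                child.parent = n.id
                child_blens.append(bl)
            assert text[pos] == ")", f"expected ')' at {pos}"
            pos += 1
            n._child_blens = child_blens  # type: ignore[attr-defined]
        # label / annotation / branch length
        m = re.match(r"([^\[\],():;]*)(\[[^\]]*\])?(?::([0-9.eE+-]+))?",
                     text[pos:])
        name, annot, blen = m.group(1), m.group(2), m.group(3)
        pos += m.end()
        if name:
            n.name = name
        if annot:
            parse_annot(n, annot)
        return n, float(blen) if blen else 0.0

    root, _ = parse(None)

    # assign times: tips at 0, parent time = child time + branch length
    def set_times(n: Node) -> float:
        if not n.children:
            n.time = 0.0
            return 0.0
        times = []
        for c, bl in zip(n.children, n._child_blens):  # type: ignore[attr-defined]
            set_times(nodes[c])
            times.append(nodes[c].time + bl)
        n.time = times[0]
        return n.time

    set_times(root)
    for n in nodes.values():
        if hasattr(n, "_child_blens"):
            del n._child_blens  # type: ignore[attr-defined]
    return EventGenealogy(nodes, root.id, locus)
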