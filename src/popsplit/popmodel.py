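"""Population models: labels, sampling, migration and divergence structure.

A :class:`PopulationModel` declares the populations, how many lineages were
sampled from each, and which backward-in-time transitions are legal: an
immigration edge ``j -> i`` lets a lineage currently in population ``i``
switch its label to ``j`` (the source of its immigrant ancestor), and a
divergence edge ``derived -> ancestral`` lets a lineage irreversibly join
the ancestral population.  No guide tree is required: several derived
populations may share one ancestor (e.g. two islands independently
colonised from a mainland), and a population may be both ancestral and
present-day.

The connection structure can be written as an ``n x n`` character matrix
(rows = receiving population, columns = source):

    ``'*'`` migration only, ``'d'`` divergence only, ``'D'`` divergence and
    migration, ``'0'`` no connection; the diagonal is ignored.

Population indices are 1-based in model files and user-facing strings and
0-based internally.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "PopulationModel",
    "ParameterSet",
    "validate_model",
    "lineage_state_targets",
    "parse_adjacency_matrix",
    "format_adjacency_matrix",
]


@dataclass(frozen=True)
class PopulationModel:
    """Populations plus the migration/divergence connection structure.

    Edges are stored as ordered pairs of 0-based population indices.
    ``migration_edges`` use the backward-time convention of the structured
    coalescent: the pair ``(j, i)`` means lineages in ``i`` may switch to
    ``j`` (rate ``M_ji``, immigrants into ``i`` from ``j`` forward in
    time).  ``divergence_edges`` run derived -> ancestral.
    """

    population_labels: tuple[str, ...]
    sample_counts: tuple[int, ...]
    migration_edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)
    divergence_edges: frozenset[tuple[int, int]] = field(default_factory=frozenset)

    def __init__(self, population_labels, sample_counts,
                 migration_edges=(), divergence_edges=()):
        object.__setattr__(self, "population_labels", tuple(population_labels))
        object.__setattr__(self, "sample_counts", tuple(int(c) for c in sample_counts))
        object.__setattr__(self, "migration_edges",
                           frozenset((int(a), int(b)) for a, b in migration_edges))
        object.__setattr__(self, "divergence_edges",
                           frozenset((int(a), int(b)) for a, b in divergence_edges))

    @property
    def n_populations(self) -> int:
        return len(self.population_labels)

    def index(self, label: str) -> int:
        try:
            return self.population_labels.index(label)
        except ValueError:
            raise KeyError(f"unknown population label: {label!r}") from None

    def ancestor_of(self, pop: int) -> int | None:
        """The divergence target of ``pop``, or None for a terminal population."""
        for derived, anc in self.divergence_edges:
            if derived == pop:
                return anc
        return None

    def migration_sources(self, pop: int) -> list[int]:
        """Populations ``j`` with an immigration edge ``j -> pop``."""
        return sorted(j for j, i in self.migration_edges if i == pop)


@dataclass(frozen=True)
class ParameterSet:
    """All rate parameters of the model, mutation-scaled.

    theta
        Per-population mutation-scaled effective size Theta_i = 4*Ne*mu.
    mig
        Mapping ``(j, i) -> M_ji`` = m_ji / mu, per immigration edge.
    div_mean, div_sd
        Mapping ``(derived, ancestral) -> `` mean / standard deviation of
        the zero-truncated normal divergence-time distribution per edge.
    b1
        Upper truncation bound shared by all divergence distributions
        (``inf`` when unbounded; the lower bound is fixed at 0).
    """

    theta: tuple[float, ...]
    mig: dict[tuple[int, int], float] = field(default_factory=dict)
    div_mean: dict[tuple[int, int], float] = field(default_factory=dict)
    div_sd: dict[tuple[int, int], float] = field(default_factory=dict)
    b1: float = float("inf")

    def __init__(self, theta, mig=None, div_mean=None, div_sd=None, b1=float("inf")):
        object.__setattr__(self, "theta", tuple(float(t) for t in theta))
        object.__setattr__(self, "mig", dict(mig or {}))
        object.__setattr__(self, "div_mean", dict(div_mean or {}))
        object.__setattr__(self, "div_sd", dict(div_sd or {}))
        object.__setattr__(self, "b1", float(b1))
        for t in self.theta:
            if not t > 0:
                raise ValueError("theta must be positive")
        for m in self.mig.values():
            if m < 0:
                raise ValueError("migration rates must be non-negative")
        for edge, mu_d in self.div_mean.items():
            if not mu_d > 0:
                raise ValueError(f"div_mean must be positive on edge {edge}")
            if not self.b1 > mu_d and self.b1 != float("inf"):
                raise ValueError("b1 must exceed every divergence mean")
        for sd in self.div_sd.values():
            if not sd > 0:
                raise ValueError("div_sd must be positive")

    def replace(self, **kw) -> "ParameterSet":
        cur = dict(theta=self.theta, mig=self.mig, div_mean=self.div_mean,
                   div_sd=self.div_sd, b1=self.b1)
        cur.update(kw)
        return ParameterSet(**cur)


def validate_model(model: PopulationModel) -> list[str]:
    """Return every structural violation of ``model`` (empty when valid).

    Violations are returned as data rather than raised, so callers can
    report all problems of a hand-written model file at once.
    """
    issues: list[str] = []
    n = model.n_populations
    if len(model.sample_counts) != n:
        issues.append(
            f"sample_counts has {len(model.sample_counts)} entries for {n} populations")
    for c in model.sample_counts:
        if c < 0:
            issues.append(f"negative sample count {c}")
    for j, i in model.migration_edges:
        if not (0 <= j < n and 0 <= i < n):
            issues.append(f"migration edge ({j + 1}->{i + 1}) references an undeclared population")
        elif j == i:
            issues.append(f"migration edge ({j + 1}->{i + 1}) is a self loop")
    out: dict[int, list[int]] = {}
    for derived, anc in model.divergence_edges:
        if not (0 <= derived < n and 0 <= anc < n):
            issues.append(
                f"divergence edge ({derived + 1}->{anc + 1}) references an undeclared population")
            continue
        if derived == anc:
            issues.append(f"divergence edge ({derived + 1}->{anc + 1}) is a self loop")
            continue
        out.setdefault(derived, []).append(anc)
    for derived, ancs in out.items():
        if len(ancs) > 1:
            issues.append(
                f"population {derived + 1} has {len(ancs)} ancestral targets; exactly one is allowed")
    # cycle check on the divergence graph (each node has <=1 outgoing edge)
    for start in out:
        seen = {start}
        cur = start
        while cur in out and len(out[cur]) == 1:
            cur = out[cur][0]
            if cur in seen:
                issues.append(
                    f"divergence edges form a cycle through population {cur + 1}")
                break
            seen.add(cur)
    return issues


def lineage_state_targets(model: PopulationModel, population: str | int):
    """Legal backward-time label switches for a lineage in ``population``.

    Returns ``(immigration_sources, divergence_target)`` where the sources
    are the populations whose immigrants the lineage may trace back to and
    the target is the ancestral population (or None).  Divergence is
    irreversible: there is never a transition back to a derived label.
    """
    pop = model.index(population) if isinstance(population, str) else int(population)
    if not (0 <= pop < model.n_populations):
        raise KeyError(f"unknown population index: {pop}")
    return model.migration_sources(pop), model.ancestor_of(pop)


def parse_adjacency_matrix(rows: list[str]):
    """Parse the character connection matrix into edge sets.

    Row ``i``, column ``j`` describes the connection from source ``j`` into
    receiver ``i``: ``'*'`` migration, ``'d'`` divergence (``i`` is derived
    from ``j``), ``'D'`` both, ``'0'`` or ``'.'`` none.  The diagonal is
    ignored.  Returns ``(migration_edges, divergence_edges)`` with 0-based
    ``(source, receiver)`` / ``(derived, ancestral)`` pairs.
    """
    n = len(rows)
    mig, div = set(), set()
    for i, row in enumerate(rows):
        cells = row.split() if " " in row.strip() else list(row.strip())
        if len(cells) != n:
            raise ValueError(f"adjacency row {i + 1} has {len(cells)} cells, expected {n}")
        for j, c in enumerate(cells):
            if i == j:
                continue
            if c == "*":
                mig.add((j, i))
            elif c == "d":
                div.add((i, j))
            elif c == "D":
                mig.add((j, i))
                div.add((i, j))
            elif c not in "0.":
                raise ValueError(f"unknown adjacency symbol {c!r} at row {i + 1}")
    return frozenset(mig), frozenset(div)


def format_adjacency_matrix(model: PopulationModel) -> list[str]:
    """Inverse of :func:`parse_adjacency_matrix` for a model's edge sets."""
    n = model.n_populations
    rows = []
    for i in range(n):
        cells = []
        for j in range(n):
            if i == j:
                cells.append("0")
                continue
            m = (j, i) in model.migration_edges
            d = (i, j) in model.divergence_edges
            cells.append("D" if (m and d) else "*" if m else "d" if d else "0")
        rows.append(" ".join(cells))
    return rows
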