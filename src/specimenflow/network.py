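"""Directed weighted country flow networks and slice-level topology metrics.

Self-loops (specimens collected and held in the same country) are kept in a
separate domestic ledger: they never enter topology metrics, but they count
toward holdings when the inequality module asks for them.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd

from .ingest import OccurrenceRecord
from .periods import PeriodSpec, default_periods


@dataclass
class FlowNetwork:
    """One family × period slice of international specimen flows."""

    family: str | None = None
    period: str | None = None
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    domestic: dict[str, int] = field(default_factory=dict)

    @property
    def nodes(self) -> set[str]:
        """Countries incident to >= 1 international edge (no isolates)."""
        out: set[str] = set()
        for o, h in self.edges:
            out.add(o)
            out.add(h)
        return out

    @property
    def slice_id(self) -> tuple[str | None, str | None]:
        return (self.family, self.period)

    def to_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for (o, h), w in self.edges.items():
            g.add_edge(o, h, weight=w)
        return g

    def total_weight(self) -> int:
        return sum(self.edges.values())


@dataclass(frozen=True)
class NetworkMetrics:
    nodes: int
    edges: int
    density: float
    reciprocity: float | None
    giant_fraction: float | None
    modularity: float | None
    edges_to_nodes: float | None


@dataclass(frozen=True)
class CountryFlowStats:
    country: str
    in_strength: int
    out_strength: int
    domestic: int
    net: int
    net_balance: float | None


def slice_records(records: list[OccurrenceRecord], family: str | None,
                  period: str | None,
                  period_spec: PeriodSpec | None = None
                  ) -> list[OccurrenceRecord]:
    spec = period_spec or default_periods()
    out = []
    for r in records:
        if family is not None and r.family != family:
            continue
        if period is not None and spec.assign(r.year) != period:
            continue
        out.append(r)
    return out


def build_flow_network(records: list[OccurrenceRecord],
                       family: str | None = None,
                       period: str | None = None,
                       period_spec: PeriodSpec | None = None) -> FlowNetwork:
    """Aggregate record counts into a per-slice flow network.

    Edge weight of (origin, holding) is the sum of specimen counts over
    matching records; origin == holding rows go to the domestic ledger.
    An empty slice yields a valid empty network.
    """
    net = FlowNetwork(family=family, period=period)
    for r in slice_records(records, family, period, period_spec):
        if r.origin_country == r.holding_country:
            net.domestic[r.origin_country] = (
                net.domestic.get(r.origin_country, 0) + r.count)
        else:
            key = (r.origin_country, r.holding_country)
            net.edges[key] = net.edges.get(key, 0) + r.count
    return net


def network_size(net: FlowNetwork) -> int:
    return len(net.nodes)


def network_complexity(net: FlowNetwork) -> int:
    return len(net.edges)


def density(net: FlowNetwork) -> float:
    """Realised fraction of possible directed edges; 0 for < 2 nodes."""
    n = network_size(net)
    if n < 2:
        return 0.0
    return len(net.edges) / (n * (n - 1))


def reciprocity(net: FlowNetwork) -> float | None:
    """Fraction of edges whose reverse edge exists (weight-blind).

    Undefined (None) on an empty edge set.
    """
    if not net.edges:
        return None
    mutual = sum(1 for (o, h) in net.edges if (h, o) in net.edges)
    return mutual / len(net.edges)


def giant_component_fraction(net: FlowNetwork) -> float | None:
    """Share of nodes in the largest weakly connected component."""
    n = network_size(net)
    if n == 0:
        return None
    g = net.to_digraph()
    largest = max(len(c) for c in nx.weakly_connected_components(g))
    return largest / n


def collapse_undirected(net: FlowNetwork) -> nx.Graph:
    """Undirected projection summing weights of antiparallel edges."""
    g = nx.Graph()
    for (o, h), w in net.edges.items():
        if g.has_edge(o, h):
            g[o][h]["weight"] += w
        else:
            g.add_edge(o, h, weight=w)
    return g


def modularity_louvain(net: FlowNetwork, seed: int,
                       restarts: int = 5) -> tuple[float, dict[str, int]]:
    """Best-of-``restarts`` Louvain modularity on the undirected projection.

    Returns (modularity, node → community-id partition).  Deterministic for
    a fixed seed; restart r uses seed + r.
    """
    if not net.edges:
        raise ValueError("modularity undefined on an empty edge set")
    g = collapse_undirected(net)
    best_q = -math.inf
    best_comms = None
    for r in range(restarts):
        comms = nx.community.louvain_communities(g, weight="weight",
                                                 seed=seed + r)
        q = nx.community.modularity(g, comms, weight="weight")
        if q > best_q:
            best_q = q
            best_comms = comms
    partition = {}
    for cid, comm in enumerate(sorted(best_comms, key=lambda c: sorted(c)[0])):
        for node in comm:
            partition[node] = cid
    return float(best_q), partition


def node_strengths(net: FlowNetwork) -> list[CountryFlowStats]:
    """Per-country weighted in/out strengths, domestic ledger and net balance.

    Covers every country in the node set plus domestic-only countries.
    net_balance is None when in + out == 0 (domestic-only participant).
    """
    in_s: dict[str, int] = {}
    out_s: dict[str, int] = {}
    for (o, h), w in net.edges.items():
        out_s[o] = out_s.get(o, 0) + w
        in_s[h] = in_s.get(h, 0) + w
    countries = sorted(net.nodes | set(net.domestic))
    stats = []
    for c in countries:
        i, o = in_s.get(c, 0), out_s.get(c, 0)
        balance = (i - o) / (i + o) if (i + o) > 0 else None
        stats.append(CountryFlowStats(
            country=c, in_strength=i, out_strength=o,
            domestic=net.domestic.get(c, 0), net=i - o, net_balance=balance))
    return stats


def top_k_edges(net: FlowNetwork, k: int) -> list[tuple[str, str, int]]:
    """k highest-weight edges; ties broken by origin then holding ISO3."""
    if k < 1:
        raise ValueError("k must be >= 1")
    ranked = sorted(net.edges.items(), key=lambda kv: (-kv[1], kv[0]))
    return [(o, h, w) for (o, h), w in ranked[:k]]


def apply_weight_threshold(net: FlowNetwork, min_weight: int) -> FlowNetwork:
    """Drop edges lighter than ``min_weight``; node set is recomputed."""
    if min_weight < 1:
        raise ValueError("min_weight must be >= 1")
    return FlowNetwork(
        family=net.family, period=net.period,
        edges={k: w for k, w in net.edges.items() if w >= min_weight},
        domestic=dict(net.domestic))


def compute_metrics(net: FlowNetwork, seed: int = 0,
                    restarts: int = 5) -> NetworkMetrics:
    n = network_size(net)
    e = network_complexity(net)
    if e:
        q, _ = modularity_louvain(net, seed=seed, restarts=restarts)
    else:
        q = None
    return NetworkMetrics(
        nodes=n, edges=e, density=density(net),
        reciprocity=reciprocity(net),
        giant_fraction=giant_component_fraction(net),
        modularity=q,
        edges_to_nodes=(e / n) if n else None)


METRIC_NAMES = ("nodes", "edges", "density", "reciprocity", "giant_fraction",
                "modularity", "edges_to_nodes")


def metrics_by_slice(records: list[OccurrenceRecord],
                     period_spec: PeriodSpec | None = None,
                     families: list[str] | None = None,
                     seed: int = 0, min_weight: int = 1) -> pd.DataFrame:
    """Tidy metrics table, one row per family × period."""
    spec = period_spec or default_periods()
    fams = families or sorted({r.family for r in records})
    rows = []
    for fam in fams:
        for p in spec.labels:
            net = build_flow_network(records, fam, p, spec)
            if min_weight > 1:
                net = apply_weight_threshold(net, min_weight)
            m = compute_metrics(net, seed=seed)
            rows.append({"family": fam, "period": p,
                         "midpoint": spec.midpoint_of(p),
                         "nodes": m.nodes, "edges": m.edges,
                         "density": m.density, "reciprocity": m.reciprocity,
                         "giant_fraction": m.giant_fraction,
                         "modularity": m.modularity,
                         "edges_to_nodes": m.edges_to_nodes})
    return pd.DataFrame(rows)
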