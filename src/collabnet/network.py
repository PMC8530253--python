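"""Projection of patient-day units into weighted clinician networks.

Two clinicians share a *tie* when both acted on the same patient's chart on
the same calendar day; the tie weight is the cumulative number of distinct
(patient, day) pairs they shared over the period.  The projection is the
one-mode projection of the bipartite clinician × patient-day incidence
structure, counted once per shared patient-day regardless of how many
actions each clinician performed.

The container is deliberately minimal (node → specialty map plus an
unordered-pair → weight map); interop with standard graph tooling goes
through :meth:`CollaborationNetwork.to_networkx` and the GraphML/GEXF/edge
list writers.
"""

from __future__ import annotations

from collections import Counter, deque
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping

import networkx as nx
import pandas as pd


class NetworkError(ValueError):
    pass


def _edge_key(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a <= b else (b, a)


@dataclass
class CollaborationNetwork:
    """Weighted undirected clinician collaboration network for one period.

    ``nodes`` maps clinician id to specialty label; ``edges`` maps the
    sorted clinician pair to its positive integer patient-day weight.
    Self-loops are forbidden; isolated nodes (clinicians with activity but
    no same-day co-occurrence) are legitimate members.
    """

    period_label: str = ""
    nodes: dict[str, str] = field(default_factory=dict)
    edges: dict[tuple[str, str], int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (a, b), w in self.edges.items():
            if a == b:
                raise NetworkError(f"self-loop on {a!r}")
            if (a, b) != _edge_key(a, b):
                raise NetworkError(f"edge key {(a, b)} not in sorted order")
            if a not in self.nodes or b not in self.nodes:
                raise NetworkError(f"edge {(a, b)} endpoint missing from nodes")
            if w <= 0:
                raise NetworkError(f"non-positive weight on edge {(a, b)}")

    # -- basic accessors ---------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def total_weight(self) -> int:
        return sum(self.edges.values())

    def weight(self, a: str, b: str) -> int:
        return self.edges.get(_edge_key(a, b), 0)

    def adjacency(self) -> dict[str, dict[str, int]]:
        """Neighbour → weight map per node (isolated nodes map to {})."""
        adj: dict[str, dict[str, int]] = {u: {} for u in self.nodes}
        for (a, b), w in self.edges.items():
            adj[a][b] = w
            adj[b][a] = w
        return adj

    def connected_components(self) -> list[list[str]]:
        """Components in deterministic order (by smallest member id)."""
        adj = self.adjacency()
        seen: set[str] = set()
        comps: list[list[str]] = []
        for u in sorted(self.nodes):
            if u in seen:
                continue
            comp = []
            q = deque([u])
            seen.add(u)
            while q:
                v = q.popleft()
                comp.append(v)
                for w in adj[v]:
                    if w not in seen:
                        seen.add(w)
                        q.append(w)
            comps.append(sorted(comp))
        return comps

    # -- interop -----------------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph(period=self.period_label)
        for node, spec in self.nodes.items():
            g.add_node(node, specialty=spec)
        for (a, b), w in self.edges.items():
            g.add_edge(a, b, weight=int(w))
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph, period_label: str = "") -> "CollaborationNetwork":
        nodes = {str(n): str(d.get("specialty", "")) for n, d in g.nodes(data=True)}
        edges = {
            _edge_key(str(a), str(b)): int(d.get("weight", 1))
            for a, b, d in g.edges(data=True)
        }
        return cls(period_label or str(g.graph.get("period", "")), nodes, edges)


def build_network(
    patient_days: pd.DataFrame,
    roster: Mapping[str, str],
    period_label: str = "",
    min_weight: int = 1,
) -> CollaborationNetwork:
    """Project patient-day units into the collaboration network.

    Parameters
    ----------
    patient_days
        Frame with columns ``clinician_id, patient_id, day`` (one period's
        distinct units, as produced by :func:`collabnet.audit_log.to_patient_days`).
    roster
        Clinician id → specialty; must cover every clinician that appears.
    min_weight
        Drop edges below this weight (default 1 = keep all).

    An edge (a, b) exists iff some (patient, day) has units for both a and
    b; its weight is the number of such shared (patient, day) pairs.  The
    node set is every clinician appearing in ``patient_days``, so clinicians
    with activity but no co-occurrence remain as isolated nodes.
    """
    clinicians = patient_days["clinician_id"].unique()
    missing = sorted(set(clinicians) - set(roster))
    if missing:
        raise NetworkError(f"clinicians missing from roster: {missing}")

    units = patient_days[["clinician_id", "patient_id", "day"]].drop_duplicates()
    weights: Counter[tuple[str, str]] = Counter()
    for _, group in units.groupby(["patient_id", "day"], sort=False):
        cs = sorted(group["clinician_id"])
        for a, b in combinations(cs, 2):
            weights[(a, b)] += 1

    edges = {k: int(w) for k, w in weights.items() if w >= min_weight}
    nodes = {c: roster[c] for c in sorted(clinicians)}
    return CollaborationNetwork(period_label, nodes, edges)


@dataclass
class NetworkStats:
    n_nodes: int
    n_edges: int
    total_weight: int
    specialty_counts: dict[str, int]
    n_components: int
    component_sizes: list[int]


def network_stats(net: CollaborationNetwork) -> NetworkStats:
    comps = net.connected_components()
    return NetworkStats(
        n_nodes=net.n_nodes,
        n_edges=net.n_edges,
        total_weight=net.total_weight,
        specialty_counts=dict(Counter(net.nodes.values())),
        n_components=len(comps),
        component_sizes=sorted((len(c) for c in comps), reverse=True),
    )


# -- writers / readers -----------------------------------------------------

def write_graphml(net: CollaborationNetwork, path: str) -> None:
    nx.write_graphml(net.to_networkx(), path)


def read_graphml(path: str, period_label: str = "") -> CollaborationNetwork:
    return CollaborationNetwork.from_networkx(nx.read_graphml(path), period_label)


def write_gexf(net: CollaborationNetwork, path: str) -> None:
    nx.write_gexf(net.to_networkx(), path)


def write_edgelist_csv(net: CollaborationNetwork, path: str) -> None:
    """Write ``source,target,weight`` rows in deterministic order."""
    rows = [
        {"source": a, "target": b, "weight": w}
        for (a, b), w in sorted(net.edges.items())
    ]
    pd.DataFrame(rows, columns=["source", "target", "weight"]).to_csv(
        path, index=False
    )


def read_edgelist_csv(
    path: str,
    roster: Mapping[str, str] | None = None,
    period_label: str = "",
) -> CollaborationNetwork:
    """Read an edge-list CSV back into a network.

    Isolated nodes are not representable in an edge list; supply ``roster``
    to restore specialty labels (missing ids get an empty label).
    """
    df = pd.read_csv(path, dtype={"source": str, "target": str})
    edges: dict[tuple[str, str], int] = {}
    nodes: dict[str, str] = {}
    for row in df.itertuples(index=False):
        a, b, w = str(row.source), str(row.target), int(row.weight)
        edges[_edge_key(a, b)] = w
        for u in (a, b):
            nodes.setdefault(u, (roster or {}).get(u, ""))
    return CollaborationNetwork(period_label, nodes, edges)


EXPORT_FORMATS = ("graphml", "gexf", "edgelist_csv")


def export_network(net: CollaborationNetwork, path: str, fmt: str) -> None:
    """Export to one of ``graphml | gexf | edgelist_csv``."""
    if fmt == "graphml":
        write_graphml(net, path)
    elif fmt == "gexf":
        write_gexf(net, path)
    elif fmt == "edgelist_csv":
        write_edgelist_csv(net, path)
    else:
        raise NetworkError(f"unknown export format {fmt!r}; use {EXPORT_FORMATS}")
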