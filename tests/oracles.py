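"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately naive — exhaustive enumeration, dense
linear algebra, O(n^3) dynamic programming — and shares no code with the
package's own algorithms.
"""

from __future__ import annotations

import itertools

import numpy as np

from collabnet.network import CollaborationNetwork


def random_connected_network(seed: int, max_nodes: int = 8) -> CollaborationNetwork:
    """Small random connected weighted graph (spanning tree + extra edges)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"v{i}" for i in range(n)]
    edges: dict[tuple[str, str], int] = {}
    order = list(rng.permutation(n))
    for i in range(1, n):
        a, b = order[i], order[int(rng.integers(0, i))]
        key = tuple(sorted((names[a], names[b])))
        edges[key] = int(rng.integers(1, 6))
    n_extra = int(rng.integers(0, n))
    for _ in range(n_extra):
        a, b = rng.choice(n, size=2, replace=False)
        key = tuple(sorted((names[a], names[b])))
        edges[key] = int(rng.integers(1, 6))
    return CollaborationNetwork("", {v: "x" for v in names}, edges)


def _dense(net: CollaborationNetwork, use_weights: bool):
    nodes = sorted(net.nodes)
    idx = {u: i for i, u in enumerate(nodes)}
    n = len(nodes)
    A = np.zeros((n, n))
    for (a, b), w in net.edges.items():
        A[idx[a], idx[b]] = A[idx[b], idx[a]] = w if use_weights else 1.0
    return nodes, A


def floyd_warshall_distances(net: CollaborationNetwork) -> tuple[list[str], np.ndarray]:
    nodes, A = _dense(net, use_weights=False)
    n = len(nodes)
    D = np.full((n, n), np.inf)
    np.fill_diagonal(D, 0.0)
    D[A > 0] = 1.0
    for k in range(n):
        D = np.minimum(D, D[:, [k]] + D[[k], :])
    return nodes, D


def eccentricity_oracle(net: CollaborationNetwork) -> dict[str, int]:
    nodes, D = floyd_warshall_distances(net)
    ecc = {}
    for i, u in enumerate(nodes):
        finite = D[i][np.isfinite(D[i])]
        ecc[u] = int(finite.max()) if len(finite) else 0
    return ecc


def betweenness_oracle(net: CollaborationNetwork) -> dict[str, float]:
    """Exhaustive shortest-path enumeration with fractional counting."""
    nodes, D = floyd_warshall_distances(net)
    idx = {u: i for i, u in enumerate(nodes)}
    adj = {u: set() for u in nodes}
    for a, b in net.edges:
        adj[a].add(b)
        adj[b].add(a)
    raw = dict.fromkeys(nodes, 0.0)

    def all_shortest_paths(s: str, t: str) -> list[list[str]]:
        if not np.isfinite(D[idx[s], idx[t]]):
            return []
        paths = []

        def extend(path):
            u = path[-1]
            if u == t:
                paths.append(path)
                return
            for v in adj[u]:
                # step must stay on a shortest path to t
                if D[idx[u], idx[t]] == D[idx[v], idx[t]] + 1:
                    extend(path + [v])

        extend([s])
        return paths

    for s, t in itertools.combinations(nodes, 2):
        paths = all_shortest_paths(s, t)
        if not paths:
            continue
        for path in paths:
            for v in path[1:-1]:
                raw[v] += 1.0 / len(paths)

    # component sizes from the distance matrix
    comp_size = {
        u: int(np.isfinite(D[idx[u]]).sum()) for u in nodes
    }
    out = {}
    for u in nodes:
        m = comp_size[u]
        norm = (m - 1) * (m - 2) / 2.0
        out[u] = raw[u] / norm if norm > 0 else 0.0
    return out


def eigenvector_oracle(net: CollaborationNetwork, use_weights: bool) -> dict[str, float]:
    """Leading eigenvector per component via a dense symmetric eigensolver."""
    nodes, A = _dense(net, use_weights)
    _, D = floyd_warshall_distances(net)
    n = len(nodes)
    seen: set[int] = set()
    scores = np.zeros(n)
    for i in range(n):
        if i in seen:
            continue
        members = [j for j in range(n) if np.isfinite(D[i, j])]
        seen.update(members)
        if len(members) == 1:
            continue
        sub = A[np.ix_(members, members)]
        vals, vecs = np.linalg.eigh(sub)
        lead = np.abs(vecs[:, np.argmax(vals)])
        scores[members] = lead / lead.max()
    return {u: float(scores[i]) for i, u in enumerate(nodes)}


def cooccurrence_oracle(patient_days) -> dict[tuple[str, str], int]:
    """Per-pair count of shared (patient, day) units, pair by pair."""
    units: dict[str, set] = {}
    for row in patient_days.itertuples(index=False):
        units.setdefault(row.clinician_id, set()).add((row.patient_id, row.day))
    weights = {}
    for a, b in itertools.combinations(sorted(units), 2):
        shared = len(units[a] & units[b])
        if shared:
            weights[(a, b)] = shared
    return weights


def mwu_enumeration_oracle(x, y) -> tuple[float, float]:
    """Exact two-sided Mann-Whitney by enumerating every labeling."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    pooled = np.concatenate([x, y])
    nx_ = len(x)
    us = []
    for comb in itertools.combinations(range(len(pooled)), nx_):
        xs = pooled[list(comb)]
        ys = np.delete(pooled, list(comb))
        us.append(sum(float(a > b) + 0.5 * float(a == b) for a in xs for b in ys))
    us = np.asarray(us)
    u_obs = sum(float(a > b) + 0.5 * float(a == b) for a in x for b in y)
    cdf = float(np.mean(us <= u_obs))
    sf = float(np.mean(us >= u_obs))
    return u_obs, min(1.0, 2.0 * min(cdf, sf))
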