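"""Per-clinician sociometrics: eigenvector centrality, betweenness, eccentricity.

All three measures are computed from first principles on the collaboration
network, per connected component:

* **Eigenvector centrality** — leading eigenvector of the (optionally
  weighted) adjacency matrix, found by shifted power iteration and
  max-normalised to 1 within each component.  A high score marks a hub:
  a clinician strongly tied to other strongly tied clinicians.
* **Betweenness centrality** — Brandes' single-source accumulation over
  unweighted (hop-count) shortest paths, with fractional counting over
  shortest-path multiplicity, normalised by (n-1)(n-2)/2 with
  component-local n.  A high score marks a bridge between otherwise
  distant parts of the care team.
* **Eccentricity** — a node's maximum hop distance to any node in its
  component (0 for isolated nodes).  Larger values mean more steps to
  reach the farthest collaborator.

Hop distances (not patient-day weights) are used for paths, and the
binary adjacency for eigenvector centrality, by default: co-occurrence
weights are similarities rather than costs, and on heavy-tailed
patient-day weights the max-normalised weighted eigenvector localises on
one dense cluster, collapsing most specialty medians toward zero.
Weighted variants of both (adjacency weights for the eigenvector,
distance = 1/weight for paths) are available as flags for sensitivity
analysis.
"""

from __future__ import annotations

import heapq
from collections import deque
from typing import Sequence

import numpy as np
import pandas as pd

from .network import CollaborationNetwork

METRICS = ("eigenvector", "betweenness", "eccentricity")


class ConvergenceError(RuntimeError):
    """Power iteration failed to converge."""


def _indexed(net: CollaborationNetwork):
    """Node list plus integer adjacency lists (neighbours, weights)."""
    nodes = sorted(net.nodes)
    index = {u: i for i, u in enumerate(nodes)}
    nbrs: list[list[int]] = [[] for _ in nodes]
    wts: list[list[float]] = [[] for _ in nodes]
    for (a, b), w in net.edges.items():
        ia, ib = index[a], index[b]
        nbrs[ia].append(ib)
        wts[ia].append(float(w))
        nbrs[ib].append(ia)
        wts[ib].append(float(w))
    return nodes, nbrs, wts


def _components(nbrs: list[list[int]]) -> np.ndarray:
    n = len(nbrs)
    comp = np.full(n, -1, dtype=int)
    cid = 0
    for s in range(n):
        if comp[s] >= 0:
            continue
        comp[s] = cid
        q = deque([s])
        while q:
            u = q.popleft()
            for v in nbrs[u]:
                if comp[v] < 0:
                    comp[v] = cid
                    q.append(v)
        cid += 1
    return comp


def eigenvector_centrality(
    net: CollaborationNetwork,
    use_weights: bool = False,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> dict[str, float]:
    """Eigenvector centrality by per-component shifted power iteration.

    Iterates x ← (A + I)x with a uniform start vector; the +I shift leaves
    eigenvectors unchanged but makes the dominant eigenvalue strictly
    largest in modulus on every connected component (bipartite components
    would otherwise oscillate between ±λ).  Convergence is declared when
    successive max-normalised iterates differ by less than ``tol`` in
    max-norm; scores are max-normalised to 1 within each component.
    Isolated nodes score 0.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if max_iter < 1:
        raise ValueError("max_iter must be >= 1")
    nodes, nbrs, wts = _indexed(net)
    comp = _components(nbrs)
    scores = np.zeros(len(nodes))

    for cid in range(comp.max() + 1 if len(nodes) else 0):
        members = np.flatnonzero(comp == cid)
        if len(members) == 1 or all(not nbrs[i] for i in members):
            continue  # isolated node -> 0
        sub = {g: l for l, g in enumerate(members)}
        m = len(members)
        A = np.zeros((m, m))
        for g in members:
            for nb, w in zip(nbrs[g], wts[g]):
                A[sub[g], sub[nb]] = w if use_weights else 1.0
        x = np.full(m, 1.0 / m)
        # Power iteration on B = A + I, accelerated by repeated squaring:
        # the k-th iterate is B^(2^k) x0, so even near-degenerate spectral
        # gaps (tightly clustered sub-teams give gap ratios ~1e-6) converge
        # in a few dozen multiplies.  B is primitive on a connected
        # component, so the limit is the unique Perron vector.
        B = A + np.eye(m)
        B /= B.max()
        converged = False
        for it in range(min(max_iter, 200)):
            y = B @ x
            y /= y.max()
            if np.max(np.abs(y - x)) < tol:
                x = y
                converged = True
                break
            x = y
            B = B @ B
            B /= B.max()
        if not converged:
            raise ConvergenceError(
                f"power iteration did not converge on component {cid} "
                f"({m} nodes) after {it + 1} squaring steps"
            )
        scores[members] = x / x.max()

    return {u: float(scores[i]) for i, u in enumerate(nodes)}


def betweenness_centrality(
    net: CollaborationNetwork,
    weighted_paths: bool = False,
) -> dict[str, float]:
    """Normalised betweenness by Brandes' algorithm.

    Shortest paths are hop-count by default; with ``weighted_paths`` the
    edge length is 1/weight (stronger ties are shorter) and Dijkstra
    replaces BFS.  Pair dependencies are divided equally over all shortest
    paths.  Scores are divided by (n-1)(n-2)/2 with component-local n;
    components of size ≤ 2 score 0.
    """
    nodes, nbrs, wts = _indexed(net)
    n = len(nodes)
    comp = _components(nbrs)
    comp_size = np.bincount(comp, minlength=comp.max() + 1 if n else 0)
    raw = np.zeros(n)

    for s in range(n):
        if not nbrs[s]:
            continue
        # single-source shortest paths with path counts
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, np.inf)
        dist[s] = 0.0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        if not weighted_paths:
            q = deque([s])
            while q:
                u = q.popleft()
                order.append(u)
                for v in nbrs[u]:
                    if dist[v] == np.inf:
                        dist[v] = dist[u] + 1
                        q.append(v)
                    if dist[v] == dist[u] + 1:
                        sigma[v] += sigma[u]
                        preds[v].append(u)
        else:
            seen = np.zeros(n, dtype=bool)
            heap = [(0.0, s)]
            while heap:
                du, u = heapq.heappop(heap)
                if seen[u]:
                    continue
                seen[u] = True
                order.append(u)
                for v, w in zip(nbrs[u], wts[u]):
                    alt = du + 1.0 / w
                    if alt < dist[v] - 1e-12:
                        dist[v] = alt
                        sigma[v] = sigma[u]
                        preds[v] = [u]
                        heapq.heappush(heap, (alt, v))
                    elif abs(alt - dist[v]) <= 1e-12 and not seen[v]:
                        sigma[v] += sigma[u]
                        preds[v].append(u)
        # accumulation in reverse finishing order
        delta = np.zeros(n)
        for u in reversed(order):
            for p in preds[u]:
                delta[p] += sigma[p] / sigma[u] * (1.0 + delta[u])
            if u != s:
                raw[u] += delta[u]

    scores = np.zeros(n)
    for i in range(n):
        m = comp_size[comp[i]]
        norm = (m - 1) * (m - 2) / 2.0
        # raw counts each unordered pair twice (once per endpoint as source)
        scores[i] = (raw[i] / 2.0) / norm if norm > 0 else 0.0
    return {u: float(scores[i]) for i, u in enumerate(nodes)}


def eccentricity(net: CollaborationNetwork) -> dict[str, int]:
    """Per-node eccentricity by BFS within each connected component."""
    nodes, nbrs, _ = _indexed(net)
    n = len(nodes)
    ecc = np.zeros(n, dtype=int)
    for s in range(n):
        if not nbrs[s]:
            continue
        dist = np.full(n, -1, dtype=int)
        dist[s] = 0
        far = 0
        q = deque([s])
        while q:
            u = q.popleft()
            far = dist[u]
            for v in nbrs[u]:
                if dist[v] < 0:
                    dist[v] = dist[u] + 1
                    q.append(v)
        ecc[s] = far
    return {u: int(ecc[i]) for i, u in enumerate(nodes)}


def compute_sociometrics(
    net: CollaborationNetwork,
    use_weights: bool = False,
    weighted_paths: bool = False,
    tol: float = 1e-10,
    max_iter: int = 10_000,
) -> pd.DataFrame:
    """All three sociometrics for one network.

    Returns a frame with columns ``clinician_id, specialty, component_id,
    eigenvector, betweenness, eccentricity``, sorted by clinician id.
    """
    nodes, nbrs, _ = _indexed(net)
    comp = _components(nbrs)
    eig = eigenvector_centrality(net, use_weights=use_weights, tol=tol,
                                 max_iter=max_iter)
    btw = betweenness_centrality(net, weighted_paths=weighted_paths)
    ecc = eccentricity(net)
    return pd.DataFrame(
        {
            "clinician_id": nodes,
            "specialty": [net.nodes[u] for u in nodes],
            "component_id": comp,
            "eigenvector": [eig[u] for u in nodes],
            "betweenness": [btw[u] for u in nodes],
            "eccentricity": [ecc[u] for u in nodes],
        }
    )


def summarize_by_specialty(
    table: pd.DataFrame,
    specialties: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-specialty n, median, mean and IQR of each metric.

    ``specialties`` fixes the rows to emit (a specialty with no clinicians
    appears with n=0 and null statistics); by default the specialties
    present in the table are used.  A final ``__network__`` row holds
    whole-network statistics.
    """
    specs = list(specialties) if specialties is not None else sorted(
        table["specialty"].unique()
    )
    rows = []
    for spec in specs + ["__network__"]:
        sub = table if spec == "__network__" else table[table["specialty"] == spec]
        row: dict[str, object] = {"specialty": spec, "n": len(sub)}
        for m in METRICS:
            vals = sub[m].to_numpy(dtype=float)
            if len(vals):
                q1, med, q3 = np.percentile(vals, [25, 50, 75])
                row.update({f"{m}_median": med, f"{m}_mean": vals.mean(),
                            f"{m}_q1": q1, f"{m}_q3": q3})
            else:
                row.update({f"{m}_median": np.nan, f"{m}_mean": np.nan,
                            f"{m}_q1": np.nan, f"{m}_q3": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)


def write_sociometrics(table: pd.DataFrame, path: str) -> None:
    cols = ["clinician_id", "specialty", "component_id"] + list(METRICS)
    table[cols].to_csv(path, index=False, float_format="%.10g")
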