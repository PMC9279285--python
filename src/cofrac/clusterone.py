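"""Greedy overlapping graph clustering by cohesiveness maximization.

A from-scratch implementation of the ClusterONE-style procedure used to
partition a scored interaction network into (possibly overlapping)
complexes. The quality of a vertex set V is its cohesiveness

    f(V) = w_in(V) / (w_in(V) + w_bound(V) + p * |V|)

where ``w_in`` is the total edge weight inside V, ``w_bound`` the total
weight crossing its boundary, and ``p`` a per-vertex penalty modelling
unobserved interactions (default 2). Growth seeds every still-unclaimed
vertex in descending weighted-degree order and repeatedly applies the
single vertex addition or removal that most increases f(V), stopping at a
local maximum. Candidates overlapping above ``omega >= 0.8`` are merged
transitively and small or sparse clusters are discarded. All tie-breaks are
lexicographic on protein id, so the procedure is deterministic.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .evaluate import overlap_omega

__all__ = [
    "Cluster",
    "cohesiveness",
    "grow_clusters",
    "merge_and_filter",
    "cluster_network",
    "weighted_density",
    "catalog_to_frame",
]

DEFAULT_PENALTY = 2.0
DEFAULT_OVERLAP = 0.8
DEFAULT_MIN_SIZE = 3
DEFAULT_MIN_DENSITY = 0.3


def _weights(graph: nx.Graph, members: Iterable[str]) -> tuple[float, float]:
    members = set(members)
    w_in = 0.0
    w_bound = 0.0
    for u in members:
        if u not in graph:
            continue
        for v, data in graph[u].items():
            w = float(data.get("weight", 1.0))
            if v in members:
                w_in += w / 2.0  # each internal edge visited twice
            else:
                w_bound += w
    return w_in, w_bound


def cohesiveness(
    graph: nx.Graph, members: Iterable[str], penalty: float = DEFAULT_PENALTY
) -> float:
    """f(V) = w_in / (w_in + w_bound + p|V|); rejected for empty V."""
    members = set(members)
    if not members:
        raise ValueError("cohesiveness of an empty vertex set is undefined")
    w_in, w_bound = _weights(graph, members)
    denom = w_in + w_bound + penalty * len(members)
    return w_in / denom if denom > 0 else 0.0


def weighted_density(graph: nx.Graph, members: Iterable[str]) -> float:
    """Total internal edge weight over the number of possible edges."""
    members = set(members)
    n = len(members)
    if n < 2:
        return 0.0
    w_in, _ = _weights(graph, members)
    return w_in / (n * (n - 1) / 2.0)


def grow_clusters(
    graph: nx.Graph, penalty: float = DEFAULT_PENALTY
) -> list[frozenset[str]]:
    """Greedy cohesiveness growth from every unclaimed vertex.

    Returns candidate clusters, each a local maximum of f(V) under single
    vertex addition/removal.
    """
    deg = {
        v: sum(float(d.get("weight", 1.0)) for d in graph[v].values())
        for v in graph.nodes
    }
    order = sorted(graph.nodes, key=lambda v: (-deg[v], v))
    claimed: set[str] = set()
    candidates: list[frozenset[str]] = []
    for seed in order:
        if seed in claimed:
            continue
        members = {seed}
        w_in, w_bound = 0.0, deg[seed]
        f = _f(w_in, w_bound, len(members), penalty)
        while True:
            best: tuple[float, str, str] | None = None  # (f_new, action, vertex)
            boundary = sorted(
                {v for u in members for v in graph[u]} - members
            )
            for v in boundary:
                conn = sum(
                    float(d.get("weight", 1.0))
                    for u, d in graph[v].items()
                    if u in members
                )
                nf = _f(
                    w_in + conn,
                    w_bound - conn + (deg[v] - conn),
                    len(members) + 1,
                    penalty,
                )
                cand = (nf, "add", v)
                if nf > f + 1e-12 and (best is None or _better(cand, best)):
                    best = cand
            if len(members) > 1:
                for v in sorted(members):
                    conn = sum(
                        float(d.get("weight", 1.0))
                        for u, d in graph[v].items()
                        if u in members and u != v
                    )
                    nf = _f(
                        w_in - conn,
                        w_bound + conn - (deg[v] - conn),
                        len(members) - 1,
                        penalty,
                    )
                    cand = (nf, "remove", v)
                    if nf > f + 1e-12 and (best is None or _better(cand, best)):
                        best = cand
            if best is None:
                break
            nf, action, v = best
            conn = sum(
                float(d.get("weight", 1.0))
                for u, d in graph[v].items()
                if u in members and u != v
            )
            if action == "add":
                members.add(v)
                w_in += conn
                w_bound += deg[v] - 2 * conn
            else:
                members.remove(v)
                w_in -= conn
                w_bound -= deg[v] - 2 * conn
            f = nf
        claimed |= members
        candidates.append(frozenset(members))
    return candidates


def _f(w_in: float, w_bound: float, size: int, penalty: float) -> float:
    denom = w_in + w_bound + penalty * size
    return w_in / denom if denom > 0 else 0.0


def _better(a: tuple[float, str, str], b: tuple[float, str, str]) -> bool:
    # higher f first; then additions before removals; then lexicographic id
    return (-a[0], a[1], a[2]) < (-b[0], b[1], b[2])


@dataclass(frozen=True)
class Cluster:
    """A predicted complex: member set with quality scores."""

    members: frozenset[str]
    cohesiveness: float
    density: float
    condition: str = ""


def merge_and_filter(
    candidates: Sequence[frozenset[str]],
    graph: nx.Graph,
    overlap_threshold: float = DEFAULT_OVERLAP,
    min_size: int = DEFAULT_MIN_SIZE,
    min_density: float = DEFAULT_MIN_DENSITY,
    penalty: float = DEFAULT_PENALTY,
    condition: str = "",
) -> list[Cluster]:
    """Transitively merge highly overlapping candidates, then filter.

    Candidate pairs with overlap ``omega(A, B) >= overlap_threshold`` are
    merged (union) transitively; merged clusters below *min_size* members or
    *min_density* weighted density are discarded.
    """
    candidates = [frozenset(c) for c in candidates if c]
    # dedup while keeping deterministic order
    seen: set[frozenset[str]] = set()
    uniq: list[frozenset[str]] = []
    for c in candidates:
        if c not in seen:
            seen.add(c)
            uniq.append(c)
    parent = list(range(len(uniq)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(uniq)):
        for j in range(i + 1, len(uniq)):
            if overlap_omega(uniq[i], uniq[j]) >= overlap_threshold:
                parent[find(i)] = find(j)
    groups: dict[int, set[str]] = {}
    for i, c in enumerate(uniq):
        groups.setdefault(find(i), set()).update(c)

    merged = sorted(groups.values(), key=lambda s: (sorted(s)))
    out = []
    for members in merged:
        if len(members) < min_size:
            continue
        dens = weighted_density(graph, members)
        if dens < min_density:
            continue
        out.append(
            Cluster(
                members=frozenset(members),
                cohesiveness=cohesiveness(graph, members, penalty),
                density=dens,
                condition=condition,
            )
        )
    out.sort(key=lambda c: (-c.cohesiveness, sorted(c.members)))
    return out


def network_graph(called_pairs: pd.DataFrame) -> nx.Graph:
    """Weighted graph from called pairs (edge weight = classifier score)."""
    g = nx.Graph()
    for a, b, s in zip(
        called_pairs["protein_a"], called_pairs["protein_b"], called_pairs["score"]
    ):
        g.add_edge(a, b, weight=float(s))
    return g


def cluster_network(
    called_pairs: pd.DataFrame,
    penalty: float = DEFAULT_PENALTY,
    overlap_threshold: float = DEFAULT_OVERLAP,
    min_size: int = DEFAULT_MIN_SIZE,
    min_density: float = DEFAULT_MIN_DENSITY,
    condition: str = "",
) -> list[Cluster]:
    """Grow, merge and filter clusters from one condition's called pairs."""
    graph = network_graph(called_pairs)
    candidates = grow_clusters(graph, penalty)
    return merge_and_filter(
        candidates,
        graph,
        overlap_threshold=overlap_threshold,
        min_size=min_size,
        min_density=min_density,
        penalty=penalty,
        condition=condition,
    )


def catalog_to_frame(clusters: Sequence[Cluster], prefix: str = "CID") -> pd.DataFrame:
    """Tabular catalog: complex_id, condition, cohesiveness, members."""
    rows = []
    for k, c in enumerate(clusters, start=1):
        rows.append(
            {
                "complex_id": f"{prefix}.{k:03d}",
                "condition": c.condition,
                "cohesiveness": c.cohesiveness,
                "density": c.density,
                "members": ";".join(sorted(c.members)),
            }
        )
    return pd.DataFrame(
        rows, columns=["complex_id", "condition", "cohesiveness", "density", "members"]
    )
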