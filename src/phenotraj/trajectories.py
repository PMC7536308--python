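"""Trajectory mining on the Mapper network.

Communities of the topology are found by maximizing (unweighted Newman)
modularity — exhaustively on small graphs, greedily with local refinement
on larger ones.  Disease-progression trajectories are the root-to-leaf
paths of a minimum spanning tree whose edge weights encode time (mean
encounter time on the shared rows) or, in benchmark mode, node-index
proximity.  Individual subjects are mapped to node sequences and assigned
to the mined trajectory with the highest Jaccard similarity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np

from phenotraj.core import ObservationTable, compress_sequence
from phenotraj.mapper import MapperGraph

logger = logging.getLogger("phenotraj")

#: Largest node count for which the exhaustive modularity search is used.
#: The number of set partitions (Bell number) grows super-exponentially;
#: B(10) ~ 1.2e5 is tractable, B(13) ~ 2.8e7 is not.
EXHAUSTIVE_MAX_NODES = 10


@dataclass
class Trajectory:
    """An ordered node-id sequence through the topology.

    ``mined`` trajectories come from the MST (no consecutive duplicates by
    construction); ``individual`` trajectories are one subject's compressed
    encounter-to-node sequence.
    """

    node_ids: list[int]
    kind: str = "mined"
    terminal_community: int | None = None
    subject: str | None = None

    def __post_init__(self) -> None:
        if not self.node_ids:
            raise ValueError("trajectory must be non-empty")
        if self.kind not in ("mined", "individual"):
            raise ValueError("kind must be 'mined' or 'individual'")

    def as_set(self) -> frozenset[int]:
        return frozenset(self.node_ids)


@dataclass
class CommunityPartition:
    """Node -> community assignment with its modularity score."""

    membership: dict[int, int]
    modularity: float
    approximate: bool = False

    def communities(self) -> list[frozenset[int]]:
        groups: dict[int, set[int]] = {}
        for n, c in self.membership.items():
            groups.setdefault(c, set()).add(n)
        return [frozenset(g) for _, g in sorted(groups.items())]


def modularity_score(graph: nx.Graph, membership: dict[int, int]) -> float:
    """Unweighted modularity Q = sum_c (e_c/m - (d_c / 2m)^2)."""
    m = graph.number_of_edges()
    if m == 0:
        return 0.0
    e_c: dict[int, int] = {}
    d_c: dict[int, int] = {}
    for u, v in graph.edges():
        if membership[u] == membership[v]:
            e_c[membership[u]] = e_c.get(membership[u], 0) + 1
    for n in graph.nodes():
        d_c[membership[n]] = d_c.get(membership[n], 0) + graph.degree(n)
    return sum(e_c.get(c, 0) / m - (d / (2.0 * m)) ** 2 for c, d in d_c.items())


def _partitions(items: list[int]):
    """Yield every set partition of ``items`` (restricted-growth order)."""
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in _partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def _exhaustive_communities(graph: nx.Graph) -> tuple[dict[int, int], float]:
    nodes = sorted(graph.nodes())
    adj = {n: set(graph.neighbors(n)) for n in nodes}
    deg = {n: graph.degree(n) for n in nodes}
    m = graph.number_of_edges()
    best_q = -np.inf
    best: list[list[int]] | None = None
    for part in _partitions(nodes):
        q = 0.0
        for block in part:
            bs = set(block)
            e_c = sum(len(adj[n] & bs) for n in block) / 2
            d_c = sum(deg[n] for n in block)
            q += e_c / m - (d_c / (2.0 * m)) ** 2
        if q > best_q + 1e-12:
            best_q, best = q, part
    assert best is not None
    return {n: c for c, block in enumerate(best) for n in block}, best_q


def _refine_local_moves(graph: nx.Graph, membership: dict[int, int]) -> dict[int, int]:
    """Hill-climb single-node moves and community merges until no gain."""
    membership = dict(membership)
    improved = True
    while improved:
        improved = False
        q0 = modularity_score(graph, membership)
        for n in sorted(graph.nodes()):
            current = membership[n]
            candidates = {membership[nb] for nb in graph.neighbors(n)}
            candidates.add(max(membership.values()) + 1)  # split off
            best_c, best_q = current, q0
            for c in sorted(candidates - {current}):
                membership[n] = c
                q = modularity_score(graph, membership)
                if q > best_q + 1e-12:
                    best_c, best_q = c, q
            membership[n] = best_c
            if best_c != current:
                q0 = best_q
                improved = True
        comms = sorted(set(membership.values()))
        for c1, c2 in combinations(comms, 2):
            trial = {n: (c1 if c == c2 else c) for n, c in membership.items()}
            q = modularity_score(graph, trial)
            if q > q0 + 1e-12:
                membership, q0 = trial, q
                improved = True
    return membership


def _greedy_communities(graph: nx.Graph) -> dict[int, int]:
    """Deterministic greedy modularity maximization.

    Runs a small portfolio of agglomerative starts — Clauset-Newman-Moore,
    Louvain with a fixed seed, and all-singletons — refines each by
    single-node moves and community merges until no gain, and keeps the
    best.  On small graphs this reliably reaches the global optimum; no
    guarantee in general, hence results are flagged approximate.
    """
    starts: list[dict[int, int]] = []
    cnm = nx.community.greedy_modularity_communities(graph)
    starts.append({n: c for c, block in enumerate(cnm) for n in block})
    louvain = nx.community.louvain_communities(graph, seed=0)
    starts.append({n: c for c, block in enumerate(louvain) for n in block})
    starts.append({n: i for i, n in enumerate(sorted(graph.nodes()))})
    best, best_q = None, -np.inf
    for membership in starts:
        refined = _refine_local_moves(graph, membership)
        # merge lookahead: a merge that loses modularity can still pay off
        # after node moves, so accept merges on the refined result
        improved = True
        while improved:
            improved = False
            q0 = modularity_score(graph, refined)
            comms = sorted(set(refined.values()))
            for c1, c2 in combinations(comms, 2):
                trial = {n: (c1 if c == c2 else c) for n, c in refined.items()}
                trial = _refine_local_moves(graph, trial)
                q = modularity_score(graph, trial)
                if q > q0 + 1e-12:
                    refined, q0 = trial, q
                    improved = True
                    break
        q = modularity_score(graph, refined)
        if q > best_q + 1e-12:
            best, best_q = refined, q
    assert best is not None
    return best


def optimal_communities(
    graph: MapperGraph | nx.Graph, exhaustive_max_nodes: int = EXHAUSTIVE_MAX_NODES
) -> CommunityPartition:
    """Partition the topology into communities by maximizing modularity.

    Graphs with at most ``exhaustive_max_nodes`` nodes are solved exactly
    by enumerating all set partitions; larger graphs use greedy
    agglomeration (Clauset-Newman-Moore) followed by single-node-move and
    merge refinement, and the result is flagged approximate.  An edgeless
    graph puts every node in its own community with Q = 0 by convention.
    """
    g = graph.to_networkx() if isinstance(graph, MapperGraph) else graph
    if g.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if g.number_of_edges() == 0:
        logger.warning("optimal_communities: edgeless graph; singleton communities, Q = 0")
        return CommunityPartition({n: i for i, n in enumerate(sorted(g.nodes()))}, 0.0)
    if g.number_of_nodes() <= exhaustive_max_nodes:
        membership, q = _exhaustive_communities(g)
        return CommunityPartition(membership, q, approximate=False)
    membership = _greedy_communities(g)
    # renumber communities by smallest member node for determinism
    order = sorted(set(membership.values()), key=lambda c: min(n for n in membership if membership[n] == c))
    remap = {c: i for i, c in enumerate(order)}
    membership = {n: remap[c] for n, c in membership.items()}
    q = modularity_score(g, membership)
    logger.info("optimal_communities: greedy+refine on %d nodes, Q = %.4f (approximate)",
                g.number_of_nodes(), q)
    return CommunityPartition(membership, q, approximate=True)


def edge_time_weights(graph: MapperGraph, time: np.ndarray) -> dict[tuple[int, int], float]:
    """Weight each edge by the mean encounter time over its shared rows."""
    time = np.asarray(time, dtype=float)
    return {e: float(np.mean(time[sorted(shared)])) for e, shared in graph.edges.items()}


def index_weights(graph: MapperGraph) -> dict[tuple[int, int], float]:
    """Weight each edge by |id(u) - id(v)|: node ids are assigned in
    bin-traversal order, so index distance reflects topological proximity."""
    return {(u, v): float(abs(u - v)) for (u, v) in graph.edges}


def minimum_spanning_tree(
    graph: MapperGraph | nx.Graph, weights: dict[tuple[int, int], float]
) -> nx.Graph:
    """Kruskal MST (a forest on disconnected graphs), deterministic ties.

    Edges are taken in lexicographic (weight, min id, max id) order so the
    output never depends on dict ordering.  Every node appears in the
    result; per connected component the tree has |V_c| - 1 edges.
    """
    if isinstance(graph, MapperGraph):
        nodes = graph.node_ids
        edge_list = [(u, v) for (u, v) in graph.edges]
    else:
        nodes = sorted(graph.nodes())
        edge_list = [(min(u, v), max(u, v)) for u, v in graph.edges()]
    tree = nx.Graph()
    tree.add_nodes_from(nodes)
    uf = nx.utils.UnionFind(nodes)
    for u, v in sorted(edge_list, key=lambda e: (weights[e], e[0], e[1])):
        if uf[u] != uf[v]:
            uf.union(u, v)
            tree.add_edge(u, v, weight=weights[(u, v)])
    return tree


def select_root(graph: MapperGraph, time: np.ndarray, tree: nx.Graph | None = None) -> int:
    """Root node for trajectory extraction: the cluster of first observations.

    Picks the node holding the most rows at the dataset's earliest time
    value (ties: lower mean member time, then lower id).  This is more
    robust than taking the node with minimal mean time outright, which a
    small node of early-but-late-stage rows can capture.  When the
    spanning tree is supplied the choice is restricted to its leaves —
    the origin of a set of root-to-leaf trajectories should itself be an
    extremity of the tree, not the interior of the earliest cluster's
    bin complex.
    """
    time = np.asarray(time, dtype=float)
    first_rows = frozenset(np.flatnonzero(time == time.min()).tolist())
    candidates = graph.node_ids
    if tree is not None and tree.number_of_nodes() > 1:
        leaves = [n for n in tree.nodes() if tree.degree(n) == 1 and n in graph.members]
        if leaves and any(graph.members[n] & first_rows for n in leaves):
            candidates = leaves

    def key(n: int):
        mem = sorted(graph.members[n])
        return (-len(graph.members[n] & first_rows), float(np.mean(time[mem])), n)

    return min(candidates, key=key)


def extract_trajectories(
    tree: nx.Graph,
    mean_time: dict[int, float],
    partition: CommunityPartition | None = None,
    root: int | None = None,
) -> list[Trajectory]:
    """Root-to-leaf paths of the (largest component of the) spanning tree.

    By default the root is the node with minimal mean encounter time (ties
    to the lowest id) — the cluster holding the earliest observations; an
    explicit ``root`` (e.g. from :func:`select_root`) overrides this.  One
    mined trajectory per leaf, sorted by terminal node id;
    ``terminal_community`` is filled from ``partition`` when given.
    """
    if tree.number_of_nodes() == 0:
        raise ValueError("empty tree")
    components = sorted(nx.connected_components(tree), key=len, reverse=True)
    if len(components) > 1:
        logger.warning("extract_trajectories: forest with %d components; using the largest",
                       len(components))
    comp = tree.subgraph(components[0])
    if root is None:
        root = min(comp.nodes(), key=lambda n: (mean_time[n], n))
    elif root not in comp:
        logger.warning("extract_trajectories: requested root %d not in largest component; "
                       "falling back to earliest node", root)
        root = min(comp.nodes(), key=lambda n: (mean_time[n], n))
    if comp.number_of_nodes() == 1:
        leaves: list[int] = []
    else:
        leaves = [n for n in comp.nodes() if comp.degree(n) == 1 and n != root]
    out: list[Trajectory] = []
    if not leaves:
        out.append(_make_mined([root], partition))
    for leaf in sorted(leaves):
        path = nx.shortest_path(comp, root, leaf)
        out.append(_make_mined(path, partition))
    return out


def _make_mined(path: list[int], partition: CommunityPartition | None) -> Trajectory:
    tc = partition.membership.get(path[-1]) if partition is not None else None
    return Trajectory(list(path), kind="mined", terminal_community=tc)


def jaccard_similarity(a: Trajectory | list[int], b: Trajectory | list[int]) -> float:
    """Set Jaccard |A∩B| / |A∪B| on node ids; order and multiplicity ignored."""
    sa = a.as_set() if isinstance(a, Trajectory) else frozenset(a)
    sb = b.as_set() if isinstance(b, Trajectory) else frozenset(b)
    if not sa or not sb:
        raise ValueError("trajectories must be non-empty")
    return len(sa & sb) / len(sa | sb)


def map_observations_to_nodes(
    graph: MapperGraph, table: ObservationTable, D: np.ndarray
) -> dict[str, Trajectory]:
    """Build each subject's individual trajectory through the topology.

    An encounter covered by several overlapping nodes is resolved to the
    node whose other members are closest on average (ties to the lowest
    node id); encounters outside the cover are dropped with a warning.
    Per subject, encounters are taken in time order and consecutive stays
    in the same node collapsed.
    """
    D = np.asarray(D, dtype=float)
    row_to_nodes: dict[int, list[int]] = {}
    for n in graph.node_ids:
        for r in graph.members[n]:
            row_to_nodes.setdefault(r, []).append(n)
    assignment: dict[int, int] = {}
    dropped = 0
    for r in range(table.n_rows):
        candidates = sorted(row_to_nodes.get(r, []))
        if not candidates:
            dropped += 1
            continue
        if len(candidates) == 1:
            assignment[r] = candidates[0]
            continue
        best, best_d = candidates[0], np.inf
        for n in candidates:
            others = sorted(graph.members[n] - {r})
            d = float(np.mean(D[r, others])) if others else 0.0
            if d < best_d - 1e-15:
                best, best_d = n, d
        assignment[r] = best
    if dropped:
        logger.warning("map_observations_to_nodes: %d rows outside the cover dropped", dropped)

    out: dict[str, Trajectory] = {}
    order = np.lexsort((np.arange(table.n_rows), table.time_days))
    for subj in table.subjects():
        rows = [r for r in order if table.subject_ids[r] == subj and r in assignment]
        if not rows:
            continue
        seq = compress_sequence([assignment[r] for r in rows])
        out[subj] = Trajectory(seq, kind="individual", subject=subj)
    return out


def assign_subjects(
    individuals: dict[str, Trajectory], mined: list[Trajectory]
) -> dict[str, tuple[int, float]]:
    """Assign every subject to the mined trajectory with highest Jaccard.

    Ties go to the lowest mined-trajectory index.  Returns subject ->
    (trajectory index, similarity).
    """
    if not mined:
        raise ValueError("need at least one mined trajectory")
    out: dict[str, tuple[int, float]] = {}
    for subj, ti in individuals.items():
        sims = [jaccard_similarity(ti, td) for td in mined]
        best = int(np.argmax(sims))  # first max -> lowest index on ties
        out[subj] = (best, sims[best])
    return out
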