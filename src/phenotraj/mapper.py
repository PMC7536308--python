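"""Mapper-style topological network construction.

Builds a network graph over encounter rows in five steps: (1) a pairwise
distance matrix, (2) two scalar lens (filter) projections, (3) an
overlapping two-dimensional cover of the lens plane, controlled by a
resolution (number of intervals) and a gain (overlap fraction), (4)
single-linkage clustering within every cover bin (the geometric scale),
and (5) a graph whose nodes are the per-bin clusters, with an edge
wherever two clusters share rows.

Default lenses are the projection onto the first right singular vector of
the (column-centred) feature matrix and the L-infinity centrality — the
distance from each point to the point farthest from it.  In benchmark mode
the two observed variables are used directly as lenses (``raw2d``).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from itertools import combinations

import networkx as nx
import numpy as np
from scipy.cluster.hierarchy import cut_tree, fcluster, linkage
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger("phenotraj")

_METRICS = ("cosine", "euclidean")
_LENS_PAIRS = ("svd+linf", "raw2d")


@dataclass
class MapperConfig:
    """Parameters of the Mapper construction.

    num_intervals (resolution) and gain apply identically to both lens
    dimensions, giving ``num_intervals**2`` overlapping rectangular bins;
    clusters_per_bin is the geometric scale.
    """

    metric: str = "cosine"
    lens_pair: str = "svd+linf"
    num_intervals: int = 7
    gain: float = 0.6
    clusters_per_bin: int = 8
    cluster_method: str = "histogram"
    prune_nested: bool = True
    random_seed: int = 0

    def __post_init__(self) -> None:
        if self.metric not in _METRICS:
            raise ValueError(f"metric must be one of {_METRICS}")
        if self.lens_pair not in _LENS_PAIRS:
            raise ValueError(f"lens_pair must be one of {_LENS_PAIRS}")
        if self.num_intervals < 1:
            raise ValueError("num_intervals must be >= 1")
        if not (0.0 < self.gain < 1.0):
            raise ValueError("gain must lie in (0, 1)")
        if self.clusters_per_bin < 1:
            raise ValueError("clusters_per_bin must be >= 1")
        if self.cluster_method not in ("histogram", "fixed"):
            raise ValueError("cluster_method must be 'histogram' or 'fixed'")


@dataclass
class MapperGraph:
    """Mapper network: nodes hold member row-index sets, edges the overlap.

    Node ids are consecutive integers assigned in bin-traversal order.
    ``edges`` maps an (u, v) pair with u < v to the shared row set, which by
    construction equals the intersection of the endpoints' member sets and
    is never empty.  ``attributes`` holds per-node named scalars
    (mean_time, majority_state, community_id, ...).
    """

    members: dict[int, frozenset[int]] = field(default_factory=dict)
    node_bins: dict[int, tuple[int, int]] = field(default_factory=dict)
    edges: dict[tuple[int, int], frozenset[int]] = field(default_factory=dict)
    attributes: dict[str, dict[int, float]] = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.members)

    @property
    def node_ids(self) -> list[int]:
        return sorted(self.members)

    def covered_rows(self) -> frozenset[int]:
        out: set[int] = set()
        for m in self.members.values():
            out |= m
        return frozenset(out)

    def nodes_of_row(self, row: int) -> list[int]:
        return [n for n, m in sorted(self.members.items()) if row in m]

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for n in self.node_ids:
            attrs = {k: v[n] for k, v in self.attributes.items() if n in v}
            g.add_node(n, size=len(self.members[n]), **attrs)
        for (u, v), shared in self.edges.items():
            g.add_edge(u, v, shared=len(shared))
        return g

    def to_json(self) -> str:
        payload = {
            "nodes": [
                {
                    "id": n,
                    "bin": list(self.node_bins.get(n, ())),
                    "members": sorted(self.members[n]),
                    "attrs": {k: v[n] for k, v in self.attributes.items() if n in v},
                }
                for n in self.node_ids
            ],
            "edges": [
                {"u": u, "v": v, "shared": sorted(s)} for (u, v), s in sorted(self.edges.items())
            ],
        }
        return json.dumps(payload, indent=1)

    @classmethod
    def from_json(cls, text: str) -> "MapperGraph":
        payload = json.loads(text)
        g = cls()
        for nd in payload["nodes"]:
            n = int(nd["id"])
            g.members[n] = frozenset(nd["members"])
            if nd.get("bin"):
                g.node_bins[n] = tuple(nd["bin"])
            for k, v in nd.get("attrs", {}).items():
                g.attributes.setdefault(k, {})[n] = v
        for ed in payload["edges"]:
            g.edges[(int(ed["u"]), int(ed["v"]))] = frozenset(ed["shared"])
        return g

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.to_networkx(), path)


def pairwise_distance(X: np.ndarray, metric: str = "cosine") -> np.ndarray:
    """Symmetric distance matrix; cosine d = 1 - x.y / (|x||y|).

    Raises
    ------
    ValueError
        Under the cosine metric when a row has zero norm (its direction,
        hence its cosine distance, is undefined).
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if metric not in _METRICS:
        raise ValueError(f"metric must be one of {_METRICS}")
    if metric == "cosine":
        norms = np.linalg.norm(X, axis=1)
        zero = np.flatnonzero(norms == 0)
        if zero.size:
            raise ValueError(f"cosine distance undefined for zero-norm row(s) {zero.tolist()}")
    if X.shape[0] == 1:
        return np.zeros((1, 1))
    D = squareform(pdist(X, metric=metric))
    np.fill_diagonal(D, 0.0)
    # pdist's cosine can go fractionally negative through round-off
    return np.maximum(D, 0.0)


def lens_linf_centrality(D: np.ndarray) -> np.ndarray:
    """L-infinity centrality: distance to the farthest other point."""
    D = np.asarray(D, dtype=float)
    if D.shape[0] == 1:
        return np.zeros(1)
    return D.max(axis=1)


def lens_svd(X: np.ndarray, center: bool = True) -> np.ndarray:
    """Projection of each row onto the first right singular vector.

    The matrix is column-centred first (``center=False`` skips this), and
    the singular vector's sign is fixed so its largest-magnitude component
    is positive, giving a reproducible orientation.  All-identical rows
    yield an all-zero lens with a logged warning.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Xc = X - X.mean(axis=0) if center else X
    if not np.any(Xc):
        logger.warning("lens_svd: degenerate (identical rows); lens is all zeros")
        return np.zeros(X.shape[0])
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    v = vt[0]
    if v[np.argmax(np.abs(v))] < 0:
        v = -v
    return Xc @ v


@dataclass
class CoverBin:
    """One rectangle of the 2-D cover with the rows whose lens values fall in it."""

    bin_id: tuple[int, int]
    lo: tuple[float, float]
    hi: tuple[float, float]
    members: frozenset[int]


def _intervals(lo: float, hi: float, n: int, gain: float) -> list[tuple[float, float]]:
    # interval length l = R / (n - (n-1) g); step s = l (1 - g): adjacent
    # intervals overlap exactly fraction g of their length and the union is
    # exactly [lo, hi].
    r = hi - lo
    if r == 0:
        return [(lo, hi)] * n
    ell = r / (n - (n - 1) * gain)
    step = ell * (1.0 - gain)
    out = []
    for i in range(n):
        a = lo + i * step
        b = a + ell
        if i == n - 1:
            b = hi
        out.append((a, b))
    return out


def build_cover(lens: np.ndarray, num_intervals: int, gain: float) -> list[CoverBin]:
    """Overlapping 2-D cover of the lens plane (closed rectangular bins).

    Intervals are closed, so a row on a boundary belongs to both adjacent
    bins — this preserves connectivity between neighbouring clusters.
    Every row falls in at least one bin.
    """
    if num_intervals < 1:
        raise ValueError("num_intervals must be >= 1")
    if not (0.0 < gain < 1.0):
        raise ValueError("gain must lie in (0, 1)")
    lens = np.atleast_2d(np.asarray(lens, dtype=float))
    if lens.shape[1] != 2:
        raise ValueError("lens must provide two values per row")
    if not np.all(np.isfinite(lens)):
        raise ValueError("lens values must be finite")
    iv1 = _intervals(lens[:, 0].min(), lens[:, 0].max(), num_intervals, gain)
    iv2 = _intervals(lens[:, 1].min(), lens[:, 1].max(), num_intervals, gain)
    eps1 = 1e-12 * max(1.0, abs(lens[:, 0]).max())
    eps2 = 1e-12 * max(1.0, abs(lens[:, 1]).max())
    bins: list[CoverBin] = []
    for i, (a1, b1) in enumerate(iv1):
        in1 = (lens[:, 0] >= a1 - eps1) & (lens[:, 0] <= b1 + eps1)
        for j, (a2, b2) in enumerate(iv2):
            in2 = (lens[:, 1] >= a2 - eps2) & (lens[:, 1] <= b2 + eps2)
            rows = frozenset(np.flatnonzero(in1 & in2).tolist())
            bins.append(CoverBin((i, j), (a1, a2), (b1, b2), rows))
    return bins


def cluster_bin(members, D: np.ndarray, k: int) -> list[frozenset[int]]:
    """Single-linkage clustering of one bin's rows, cut to min(k, |bin|) clusters.

    The distance matrix ``D`` is global; it is restricted to the bin's
    members here.  The returned clusters partition the bin.
    """
    rows = sorted(members)
    if not rows:
        return []
    if len(rows) == 1:
        return [frozenset(rows)]
    k_eff = min(k, len(rows))
    sub = np.asarray(D, dtype=float)[np.ix_(rows, rows)]
    Z = linkage(squareform(sub, checks=False), method="single")
    labels = cut_tree(Z, n_clusters=k_eff).ravel()
    clusters: dict[int, set[int]] = {}
    for local, lab in enumerate(labels):
        clusters.setdefault(int(lab), set()).add(rows[local])
    # order clusters by smallest member for a deterministic node order
    return [frozenset(c) for c in sorted(clusters.values(), key=min)]


def cluster_bin_gap(members, D: np.ndarray, num_bins: int) -> list[frozenset[int]]:
    """Single-linkage clustering cut at the first gap in the merge heights.

    The canonical Mapper heuristic: histogram the single-linkage merge
    heights into ``num_bins`` bins spanning up to the bin's diameter and
    cut the dendrogram at the first empty histogram bin.  A bin whose
    points form one dense blob yields a single cluster, while genuinely
    separated groups split — the cluster count adapts to the data instead
    of being forced, so isolated tail points are not shaved off into
    singleton nodes.  ``num_bins`` plays the role of the geometric-scale
    parameter: more bins detect finer gaps, giving more clusters.
    """
    rows = sorted(members)
    if not rows:
        return []
    if len(rows) == 1:
        return [frozenset(rows)]
    sub = np.asarray(D, dtype=float)[np.ix_(rows, rows)]
    Z = linkage(squareform(sub, checks=False), method="single")
    heights = Z[:, 2]
    diam = float(sub.max())
    if diam <= 0:  # all points identical
        return [frozenset(rows)]
    edges = np.linspace(heights.min(), diam, num_bins + 1)
    counts, _ = np.histogram(heights, bins=edges)
    empty = np.flatnonzero(counts == 0)
    if empty.size == 0:
        return [frozenset(rows)]
    cutoff = edges[empty[0]]
    labels = fcluster(Z, t=cutoff, criterion="distance")
    clusters: dict[int, set[int]] = {}
    for local, lab in enumerate(labels):
        clusters.setdefault(int(lab), set()).add(rows[local])
    return [frozenset(c) for c in sorted(clusters.values(), key=min)]


def build_mapper_graph(
    bin_clusters: list[tuple[tuple[int, int], list[frozenset[int]]]],
    prune_nested: bool = False,
) -> MapperGraph:
    """Assemble the network from per-bin cluster lists.

    One node per cluster, ids consecutive in (bin order, cluster order);
    an edge joins every pair of nodes whose member sets intersect, with the
    intersection as payload.  No self-edges.

    With ``prune_nested`` a cluster whose member set is contained in
    another cluster's is dropped (ids are reassigned consecutively in the
    same traversal order).  Such nested clusters contribute nothing to the
    cover's union; they arise when a cover-rectangle edge slices off the
    margin of a dense region that a neighbouring, overlapping rectangle
    already captures whole, and they would otherwise hang off the network
    as spurious dead-end nodes.
    """
    raw: list[tuple[tuple[int, int], frozenset[int]]] = []
    for bin_id, clusters in bin_clusters:
        for cluster in clusters:
            if cluster:
                raw.append((tuple(bin_id), frozenset(cluster)))
    if prune_nested:
        keep: list[bool] = []
        for i, (_, mem) in enumerate(raw):
            nested = any(
                mem < other or (mem == other and j < i)
                for j, (_, other) in enumerate(raw)
                if j != i
            )
            keep.append(not nested)
        raw = [rc for rc, k in zip(raw, keep) if k]
    g = MapperGraph()
    row_to_nodes: dict[int, list[int]] = {}
    for node_id, (bin_id, cluster) in enumerate(raw):
        g.members[node_id] = cluster
        g.node_bins[node_id] = bin_id
        for r in cluster:
            row_to_nodes.setdefault(r, []).append(node_id)
    pairs: set[tuple[int, int]] = set()
    for nodes in row_to_nodes.values():
        for u, v in combinations(nodes, 2):
            pairs.add((u, v) if u < v else (v, u))
    for u, v in sorted(pairs):
        shared = g.members[u] & g.members[v]
        if shared:
            g.edges[(u, v)] = shared
    return g


def enrich_nodes(graph: MapperGraph, values, agg: str = "mean", name: str | None = None) -> MapperGraph:
    """Attach a per-node scalar computed over member rows.

    ``mean`` is the arithmetic mean; ``majority`` the modal value with ties
    broken toward the smallest value.  The attribute is stored under
    ``name`` (default: the aggregation name) and the same graph returned.
    """
    values = np.asarray(values)
    if agg not in ("mean", "majority"):
        raise ValueError("agg must be 'mean' or 'majority'")
    name = name or agg
    attr: dict[int, float] = {}
    for n, mem in graph.members.items():
        vals = values[sorted(mem)]
        if agg == "mean":
            attr[n] = float(np.mean(vals))
        else:
            uniq, counts = np.unique(vals, return_counts=True)
            attr[n] = float(uniq[np.flatnonzero(counts == counts.max())[0]])
    graph.attributes[name] = attr
    return graph


def build_mapper(
    X: np.ndarray, config: MapperConfig, D: np.ndarray | None = None
) -> tuple[MapperGraph, np.ndarray]:
    """Run the full Mapper construction on a row-feature matrix.

    Returns the graph and the (n, 2) lens values used for the cover.  A
    precomputed distance matrix may be passed to avoid recomputation when
    scanning parameter grids.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if D is None:
        D = pairwise_distance(X, config.metric)
    if config.lens_pair == "svd+linf":
        lens = np.column_stack([lens_svd(X), lens_linf_centrality(D)])
    else:
        if X.shape[1] < 2:
            raise ValueError("raw2d lens requires at least two feature columns")
        lens = X[:, :2].copy()
    cover = build_cover(lens, config.num_intervals, config.gain)
    cluster_fn = cluster_bin_gap if config.cluster_method == "histogram" else cluster_bin
    bin_clusters = [(b.bin_id, cluster_fn(b.members, D, config.clusters_per_bin)) for b in cover]
    graph = build_mapper_graph(bin_clusters, prune_nested=config.prune_nested)
    logger.info(
        "build_mapper: %d rows -> %d nodes, %d edges (intervals=%d gain=%.2f k=%d metric=%s lens=%s)",
        X.shape[0], graph.n_nodes, len(graph.edges), config.num_intervals, config.gain,
        config.clusters_per_bin, config.metric, config.lens_pair,
    )
    return graph, lens
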