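"""Bootstrapped pseudo-time-series (PTS).

A pseudo-time-series orders cross-sectional encounters along a plausible
disease course without using any timestamps: a random sub-sample is drawn,
a complete weighted graph is built on it under the cosine metric, its
minimum spanning tree is taken, and the unique tree path from a randomly
chosen complication-free encounter (label 0) to a randomly chosen
encounter with a complication (label 1) is returned.  Repeating the
resampling yields an ensemble of series that can train a state-space
model of progression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from phenotraj.core import ObservationTable
from phenotraj.mapper import pairwise_distance

logger = logging.getLogger("phenotraj")

DEFAULT_SAMPLE_SIZE = 200
MAX_LABEL_RETRIES = 20


@dataclass
class PseudoTimeSeries:
    """Ordered encounter row indices forming one MST path.

    The first row carries label 0 (disease-free start) and the last label 1
    (diseased end); consecutive rows are adjacent in the iteration's tree
    and no row repeats (tree paths are simple).
    """

    row_indices: list[int]
    start_label: int = 0
    end_label: int = 1

    def __len__(self) -> int:
        return len(self.row_indices)


def _tree_path(adj: dict[int, list[int]], start: int, end: int) -> list[int]:
    """Unique simple path between two nodes of a tree (iterative DFS)."""
    parent = {start: start}
    stack = [start]
    while stack:
        u = stack.pop()
        if u == end:
            break
        for v in adj[u]:
            if v not in parent:
                parent[v] = u
                stack.append(v)
    path = [end]
    while path[-1] != start:
        path.append(parent[path[-1]])
    return path[::-1]


def _mst_adjacency(rows: np.ndarray, D: np.ndarray) -> dict[int, list[int]]:
    """Kruskal MST over the complete graph on ``rows``; deterministic ties
    by (weight, min row id, max row id).  Returns adjacency on row ids."""
    k = len(rows)
    iu, ju = np.triu_indices(k, 1)
    w = D[iu, ju]
    u_ids = np.minimum(rows[iu], rows[ju])
    v_ids = np.maximum(rows[iu], rows[ju])
    order = np.lexsort((v_ids, u_ids, w))
    import networkx as nx

    uf = nx.utils.UnionFind(rows.tolist())
    adj: dict[int, list[int]] = {int(r): [] for r in rows}
    taken = 0
    for idx in order:
        u, v = int(u_ids[idx]), int(v_ids[idx])
        if uf[u] != uf[v]:
            uf.union(u, v)
            adj[u].append(v)
            adj[v].append(u)
            taken += 1
            if taken == k - 1:
                break
    return adj


def generate_single_pts(
    table: ObservationTable,
    metric: str = "cosine",
    sample_size: int | None = None,
    rng_seed: int = 0,
    max_retries: int = MAX_LABEL_RETRIES,
) -> PseudoTimeSeries:
    """One bootstrap iteration: sample, complete graph, MST, start-end path.

    ``sample_size`` rows are drawn uniformly without replacement (default
    min(200, n)); the draw is retried up to ``max_retries`` times if it
    misses a label class, then a ``ValueError`` is raised.  Start and end
    are drawn uniformly among the sampled label-0 and label-1 rows.
    """
    n = table.n_rows
    if sample_size is None:
        sample_size = min(DEFAULT_SAMPLE_SIZE, n)
    if sample_size > n:
        raise ValueError(f"sample_size {sample_size} exceeds table size {n}")
    if sample_size < 2:
        raise ValueError("sample_size must be at least 2")
    rng = np.random.default_rng(rng_seed)
    for _ in range(max_retries):
        rows = np.sort(rng.choice(n, size=sample_size, replace=False))
        labels = table.labels[rows]
        if labels.min() == 0 and labels.max() == 1:
            break
    else:
        raise ValueError(f"no sample with both label classes after {max_retries} draws")
    D = pairwise_distance(table.features[rows], metric)
    adj = _mst_adjacency(rows, D)
    start = int(rng.choice(rows[labels == 0]))
    end = int(rng.choice(rows[labels == 1]))
    path = _tree_path(adj, start, end)
    return PseudoTimeSeries(path)


def generate_pts_ensemble(
    table: ObservationTable,
    metric: str = "cosine",
    sample_size: int | None = None,
    B: int = 1000,
    base_seed: int = 0,
) -> list[PseudoTimeSeries]:
    """B independent pseudo-time-series with per-iteration seeds base_seed + i.

    Iterations whose samples never span both label classes are skipped and
    counted; if every iteration fails, an error is raised.  The ensemble
    is fully reproducible from ``base_seed``.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    out: list[PseudoTimeSeries] = []
    skipped = 0
    for i in range(B):
        try:
            out.append(generate_single_pts(table, metric, sample_size, rng_seed=base_seed + i))
        except ValueError as exc:
            skipped += 1
            logger.warning("generate_pts_ensemble: iteration %d skipped (%s)", i, exc)
    if not out:
        raise ValueError("every PTS iteration failed")
    if skipped:
        logger.warning("generate_pts_ensemble: %d of %d iterations skipped", skipped, B)
    logger.info("generate_pts_ensemble: %d series (sample_size=%s, base_seed=%d)",
                len(out), sample_size, base_seed)
    return out


def series_to_sequences(series: list[PseudoTimeSeries], features: np.ndarray) -> list[np.ndarray]:
    """Materialize each series as an ordered observation matrix for model fitting."""
    features = np.atleast_2d(np.asarray(features, dtype=float))
    return [features[s.row_indices] for s in series]
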