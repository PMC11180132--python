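"""Cell-graph barrier scoring.

A spatial graph is built on cell centroids (Delaunay triangulation pruned
at a maximum edge length, by default, or a kNN graph).  For every cell of a
*source* type, an unweighted breadth-first search finds the shortest path
length to the nearest *target*-type cell; all shortest paths of that length
ending in a target cell are enumerated (capped).  Barrier metrics count
*barrier*-type cells among the path intermediates:

* ``barrier_count`` / ``barrier_fraction`` — barrier intermediates along
  the path (fraction of intermediates; endpoints excluded);
* ``adjacent_count`` / ``adjacent_fraction`` — whether the intermediate
  whose next hop is the terminal target cell is of the barrier type;
* ``all_paths_*`` — the same quantities averaged over every enumerated
  shortest path (the *all-paths* scores); the mean all-paths adjacent
  barrier fraction over source cells is the headline image-level score.

Single-path metrics are reported for the lexicographically smallest node
sequence (deterministic tie-break); summaries use the population (n)
standard deviation and cover reachable sources only.
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.spatial import Delaunay, QhullError

from .errors import ValidationError

logger = logging.getLogger("cytoplex")

_METRICS = ("barrier_count", "barrier_fraction", "adjacent_count",
            "adjacent_fraction", "all_paths_barrier_count",
            "all_paths_barrier_fraction", "all_paths_adjacent_count",
            "all_paths_adjacent_fraction")


@dataclass
class SpatialGraph:
    """Undirected cell graph: nodes are cells, edges spatial adjacency."""

    cell_ids: np.ndarray
    types: np.ndarray
    coords: np.ndarray
    adjacency: list[np.ndarray]          # sorted neighbour indices per node
    method: str
    params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        return len(self.cell_ids)

    @property
    def n_edges(self) -> int:
        return sum(len(a) for a in self.adjacency) // 2

    def edges(self) -> Iterable[tuple[int, int]]:
        for i, neigh in enumerate(self.adjacency):
            for j in neigh:
                if i < j:
                    yield i, int(j)


def _dedupe_coords(coords: np.ndarray) -> np.ndarray:
    """Stable lexicographic perturbation (1e-6 µm steps) of duplicate
    coordinates so the triangulation is well defined; logged."""
    out = coords.astype(float).copy()
    seen: dict[tuple[float, float], int] = {}
    n_dup = 0
    for i, (x, y) in enumerate(out):
        key = (x, y)
        k = seen.get(key, 0)
        seen[key] = k + 1
        if k:
            out[i, 0] += 1e-6 * k
            out[i, 1] += 1e-6 * k
            n_dup += 1
    if n_dup:
        logger.info("perturbed %d duplicate coordinate(s) by 1e-6 µm steps", n_dup)
    return out


def _collinear_chain(coords: np.ndarray) -> set[tuple[int, int]]:
    """Degenerate Delaunay limit for (near-)collinear points: consecutive
    neighbours along the principal direction."""
    d = coords - coords.mean(axis=0)
    # principal axis via the larger-spread coordinate combination
    _, _, vt = np.linalg.svd(d, full_matrices=False)
    t = d @ vt[0]
    order = np.argsort(t, kind="stable")
    return {(min(a, b), max(a, b))
            for a, b in zip(order[:-1], order[1:])}


def build_graph(cells: pd.DataFrame, method: str = "delaunay",
                max_edge_length: float = 50.0, k: int = 10,
                mutual: bool = False) -> SpatialGraph:
    """Build the cell spatial graph from a table with columns
    cell_id, label (phenotype), x, y.

    Delaunay mode prunes triangulation edges longer than
    ``max_edge_length`` microns (default 50); kNN mode connects each cell
    to its k nearest neighbours (``mutual=True`` keeps only reciprocated
    edges).  Deterministic; no self-edges.
    """
    if len(cells) < 2:
        raise ValidationError("build_graph requires at least 2 cells")
    coords = cells[["x", "y"]].to_numpy(dtype=float)
    if not np.isfinite(coords).all():
        raise ValidationError("non-finite coordinates in cell table")
    coords = _dedupe_coords(coords)
    n = len(coords)
    edges: set[tuple[int, int]] = set()
    if method == "delaunay":
        if n == 2:
            edges = {(0, 1)}
        else:
            try:
                tri = Delaunay(coords)
                for simplex in tri.simplices:
                    for a in range(3):
                        for b in range(a + 1, 3):
                            i, j = int(simplex[a]), int(simplex[b])
                            edges.add((min(i, j), max(i, j)))
            except QhullError:
                edges = _collinear_chain(coords)
        if max_edge_length is not None:
            edges = {(i, j) for i, j in edges
                     if np.hypot(*(coords[i] - coords[j])) <= max_edge_length}
    elif method == "knn":
        from sklearn.neighbors import NearestNeighbors
        nn = NearestNeighbors(n_neighbors=min(k + 1, n)).fit(coords)
        ind = nn.kneighbors(return_distance=False)
        directed = {(i, int(j)) for i in range(n) for j in ind[i] if i != j}
        for i, j in directed:
            if not mutual or (j, i) in directed:
                edges.add((min(i, j), max(i, j)))
    else:
        raise ValidationError(f"unknown graph method {method!r}")

    adjacency: list[list[int]] = [[] for _ in range(n)]
    for i, j in edges:
        adjacency[i].append(j)
        adjacency[j].append(i)
    adj = [np.array(sorted(a), dtype=int) for a in adjacency]
    return SpatialGraph(cells["cell_id"].to_numpy(), cells["label"].to_numpy(),
                        coords, adj, method,
                        {"max_edge_length": max_edge_length, "k": k,
                         "mutual": mutual})


def _bfs_to_targets(graph: SpatialGraph, source: int, is_target: np.ndarray
                    ) -> tuple[int, np.ndarray]:
    """Distance from ``source`` to the nearest target node, plus the
    distance array restricted to explored levels (-1 = unexplored).
    Returns (-1, dist) when unreachable."""
    dist = np.full(graph.n_nodes, -1, dtype=int)
    dist[source] = 0
    q = deque([source])
    found_level = -1
    while q:
        u = q.popleft()
        if found_level >= 0 and dist[u] >= found_level:
            continue  # finish the found level, no deeper
        for v in graph.adjacency[u]:
            if dist[v] < 0:
                dist[v] = dist[u] + 1
                if is_target[v] and found_level < 0 and dist[v] > 0:
                    found_level = dist[v]
                q.append(v)
    return found_level, dist


def _enumerate_paths(graph: SpatialGraph, source: int, dist: np.ndarray,
                     targets: Sequence[int], max_paths: int) -> list[list[int]]:
    """All shortest paths source→(any target), lexicographic node order,
    capped at ``max_paths`` (logged when hit)."""
    paths: list[list[int]] = []
    for t in sorted(targets):
        # DFS backwards over the BFS predecessor DAG, smallest index first
        stack: list[list[int]] = [[t]]
        while stack:
            part = stack.pop()
            u = part[-1]
            if u == source:
                paths.append(part[::-1])
                if len(paths) >= max_paths:
                    logger.info("path cap %d reached for one source; all-paths "
                                "means use the enumerated subset", max_paths)
                    return paths
                continue
            preds = [int(v) for v in graph.adjacency[u] if dist[v] == dist[u] - 1]
            for v in sorted(preds, reverse=True):  # pop order = ascending
                stack.append(part + [v])
    return paths


def _path_metrics(path: list[int], is_barrier: np.ndarray) -> tuple[int, float, int, float]:
    intermediates = path[1:-1]
    n_int = len(intermediates)
    b_count = int(sum(is_barrier[v] for v in intermediates))
    adj = int(n_int > 0 and bool(is_barrier[path[-2]]))
    denom = max(1, n_int)
    return b_count, b_count / denom, adj, adj / denom


def score_barrier(graph: SpatialGraph, source_type: str, barrier_type: str,
                  target_type: str, max_paths: int = 1000,
                  allowed_target_ids: Sequence | None = None) -> pd.DataFrame:
    """Per-source barrier records for one (source, barrier, target) triplet.

    ``allowed_target_ids`` restricts target cells (e.g. to members of
    spatial clusters above a size threshold).  Unreachable sources are
    flagged and excluded from summaries.  With no barrier-type cell in the
    graph every metric is 0.
    """
    sources = np.flatnonzero(graph.types == source_type)
    is_target = graph.types == target_type
    if allowed_target_ids is not None:
        allowed = set(allowed_target_ids)
        is_target &= np.fromiter((cid in allowed for cid in graph.cell_ids),
                                 dtype=bool, count=graph.n_nodes)
    is_barrier = graph.types == barrier_type
    if not is_target.any():
        logger.warning("no target cells of type %r; every source is unreachable",
                       target_type)
    rows = []
    for s in sources:
        rec = {"cell_id": graph.cell_ids[s], "source_type": source_type,
               "barrier_type": barrier_type, "target_type": target_type}
        level, dist = _bfs_to_targets(graph, s, is_target)
        if level < 0:
            rec.update({"reachable": False, "path_length": -1, "n_paths": 0,
                        "path_types": ""})
            rec.update({m: np.nan for m in _METRICS})
            rows.append(rec)
            continue
        targets = [int(t) for t in np.flatnonzero(is_target & (dist == level))]
        paths = _enumerate_paths(graph, s, dist, targets, max_paths)
        per_path = np.array([_path_metrics(p, is_barrier) for p in paths])
        rep = min(paths)  # lexicographically smallest node sequence
        bc, bf, ac, af = _path_metrics(rep, is_barrier)
        means = per_path.mean(axis=0)
        rec.update({
            "reachable": True, "path_length": level, "n_paths": len(paths),
            "path_types": ";".join(str(graph.types[v]) for v in rep),
            "barrier_count": bc, "barrier_fraction": bf,
            "adjacent_count": ac, "adjacent_fraction": af,
            "all_paths_barrier_count": means[0],
            "all_paths_barrier_fraction": means[1],
            "all_paths_adjacent_count": means[2],
            "all_paths_adjacent_fraction": means[3],
        })
        rows.append(rec)
    cols = ["cell_id", "source_type", "barrier_type", "target_type", "reachable",
            "path_length", "n_paths", "path_types", *_METRICS]
    return pd.DataFrame(rows, columns=cols)


def summarise(records: pd.DataFrame, image_id: str = "") -> pd.DataFrame:
    """Per-image summary: n sources, n reachable, and mean / median /
    population-std of every metric over reachable sources.

    Zero reachable sources yield a null row with n_reachable = 0."""
    reach = records[records["reachable"] == True]  # noqa: E712
    base = {"image_id": image_id,
            "n_source": len(records), "n_reachable": len(reach)}
    if records.empty:
        base.update({"source_type": "", "barrier_type": "", "target_type": ""})
    else:
        base.update({k: records.iloc[0][k]
                     for k in ("source_type", "barrier_type", "target_type")})
    rows = []
    for metric in _METRICS:
        row = dict(base)
        row["metric"] = metric
        if len(reach):
            vals = reach[metric].to_numpy(dtype=float)
            row.update({"mean": float(vals.mean()),
                        "median": float(np.median(vals)),
                        "std": float(vals.std(ddof=0))})
        else:
            row.update({"mean": np.nan, "median": np.nan, "std": np.nan})
        rows.append(row)
    return pd.DataFrame(rows)


def barrier_score(summary: pd.DataFrame) -> float:
    """The headline image-level score: mean all-paths adjacent barrier
    fraction over reachable source cells."""
    row = summary[summary["metric"] == "all_paths_adjacent_fraction"]
    return float(row["mean"].iloc[0])
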