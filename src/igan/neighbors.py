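"""Spatial adjacency and ordered cell-pair collection.

Two cells are adjacent when their Euclidean distance is positive and at most
a platform-dependent threshold: for bead platforms (near-cellular resolution,
irregular packing) the 99th percentile of per-cell nearest-neighbor distances,
robust to stray beads; for regular 10x-style grids the minimum pairwise
distance, i.e. the grid pitch.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree

from .io import SpatialDataset


class NoPairsError(ValueError):
    """No adjacent cell pairs exist for the requested type combination."""


def threshold_distance(coords: np.ndarray, platform: str = "bead") -> float:
    """Adjacency threshold for a set of 2-D coordinates.

    bead: 99th percentile (linear interpolation) of each cell's nearest-neighbor
    distance.  grid10x: minimum over all pairwise distances (the grid pitch).
    """
    coords = np.asarray(coords, dtype=float)
    if len(coords) < 2:
        raise ValueError("need at least 2 cells to define a threshold distance")
    tree = cKDTree(coords)
    d, _ = tree.query(coords, k=2)
    nearest = d[:, 1]
    if platform == "grid10x":
        thr = float(nearest.min())
    elif platform == "bead":
        thr = float(np.percentile(nearest, 99, method="linear"))
    else:
        raise ValueError(f"unknown platform {platform!r}")
    if thr == 0:
        raise ValueError("threshold distance is zero (coincident cells)")
    return thr


@dataclass
class NeighborGraph:
    """Undirected spatial adjacency: per-cell neighbor lists and degrees."""

    threshold: float
    adjacency: list[np.ndarray]  # sorted neighbor indices per cell
    edges: np.ndarray            # (n_edges, 2) with i < j
    distances: np.ndarray        # per-edge distance

    @property
    def n_cells(self) -> int:
        return len(self.adjacency)

    @property
    def t(self) -> np.ndarray:
        """Per-cell neighbor count t_a."""
        return np.array([len(a) for a in self.adjacency], dtype=int)


def build_neighbor_graph(
    dataset_or_coords: SpatialDataset | np.ndarray,
    threshold: float | None = None,
    platform: str | None = None,
) -> NeighborGraph:
    """Adjacency graph: a,b adjacent iff 0 < d(a,b) <= threshold.

    ``threshold`` defaults to :func:`threshold_distance` for the dataset's
    platform.  Isolated cells are kept with t_a = 0.
    """
    if isinstance(dataset_or_coords, SpatialDataset):
        coords = dataset_or_coords.coords
        platform = platform or dataset_or_coords.platform
    else:
        coords = np.asarray(dataset_or_coords, dtype=float)
        platform = platform or "bead"
    if threshold is None:
        threshold = threshold_distance(coords, platform)
    tree = cKDTree(coords)
    pairs = tree.query_pairs(r=threshold, output_type="ndarray")
    if len(pairs):
        d = np.linalg.norm(coords[pairs[:, 0]] - coords[pairs[:, 1]], axis=1)
        keep = d > 0  # coincident cells are not neighbors
        pairs, d = pairs[keep], d[keep]
    else:
        pairs = np.empty((0, 2), dtype=int)
        d = np.empty(0)
    order = np.lexsort((pairs[:, 1], pairs[:, 0])) if len(pairs) else np.empty(0, int)
    pairs, d = pairs[order], d[order]
    n = len(coords)
    adjacency: list[list[int]] = [[] for _ in range(n)]
    for i, j in pairs:
        adjacency[i].append(j)
        adjacency[j].append(i)
    adj = [np.array(sorted(a), dtype=int) for a in adjacency]
    return NeighborGraph(threshold=float(threshold), adjacency=adj, edges=pairs, distances=d)


@dataclass
class CellPairSet:
    """Ordered adjacent pairs (a_k, b_k) with type(a)=A, type(b)=B."""

    source_type: str
    target_type: str
    a: np.ndarray  # cell indices, length n
    b: np.ndarray

    @property
    def n(self) -> int:
        return len(self.a)


def collect_cell_pairs(graph: NeighborGraph, cell_type: np.ndarray, A: str, B: str) -> CellPairSet:
    """All ordered adjacent pairs (a, b) with type(a)=A and type(b)=B.

    When A == B both orientations of each undirected edge are included.
    Raises :class:`NoPairsError` when no such pair exists so callers can skip
    the type combination.
    """
    cell_type = np.asarray(cell_type, dtype=object)
    for t in (A, B):
        if t not in cell_type:
            raise NoPairsError(f"cell type {t!r} not present")
    e = graph.edges
    if len(e) == 0:
        raise NoPairsError(f"no adjacent ({A},{B}) pairs")
    ta, tb = cell_type[e[:, 0]], cell_type[e[:, 1]]
    fwd = (ta == A) & (tb == B)
    rev = (ta == B) & (tb == A)
    a_idx = np.concatenate([e[fwd, 0], e[rev, 1]])
    b_idx = np.concatenate([e[fwd, 1], e[rev, 0]])
    order = np.lexsort((b_idx, a_idx))
    a_idx, b_idx = a_idx[order], b_idx[order]
    if len(a_idx) == 0:
        raise NoPairsError(f"no adjacent ({A},{B}) pairs")
    return CellPairSet(source_type=A, target_type=B, a=a_idx, b=b_idx)


def all_cell_pair_sets(graph: NeighborGraph, cell_type: np.ndarray) -> dict[tuple[str, str], CellPairSet]:
    """CellPairSet for every ordered type pair that has at least one edge."""
    types = sorted(set(np.asarray(cell_type, dtype=object)))
    out: dict[tuple[str, str], CellPairSet] = {}
    for A in types:
        for B in types:
            try:
                out[(A, B)] = collect_cell_pairs(graph, cell_type, A, B)
            except NoPairsError:
                continue
    return out
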