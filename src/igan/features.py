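"""CCC feature matrix and communication-based cell clustering.

The feature matrix F has one row per cell and 2p columns for p ligands:
columns 1..p are the per-ligand sending features, p+1..2p the receiving
features, exactly as stored in the activity table.  Clustering standardizes
the features (log1p then per-feature z-score), reduces with PCA, builds a
shared-nearest-neighbor graph and partitions it with seed-fixed Leiden
modularity optimization; a combined mode concatenates expression PCs with
weighted CCC-feature PCs before graph construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import igraph as ig
import leidenalg
import numpy as np
import pandas as pd
from scipy import sparse
from sklearn.decomposition import PCA
from sklearn.metrics import adjusted_rand_score
from sklearn.neighbors import NearestNeighbors

from .activity import ActivityTable

logger = logging.getLogger(__name__)

MODES = ("ccc_only", "expression_only", "combined")


@dataclass
class CCCFeatureMatrix:
    """n_cells x 2p feature matrix; column order [send_1..send_p, recv_1..recv_p]."""

    F: np.ndarray
    cell_ids: list[str]
    ligands: list[str]

    @property
    def p(self) -> int:
        return len(self.ligands)

    def to_frame(self) -> pd.DataFrame:
        cols = [f"send:{l}" for l in self.ligands] + [f"recv:{l}" for l in self.ligands]
        return pd.DataFrame(self.F, index=pd.Index(self.cell_ids, name="cell_id"), columns=cols)


def build_feature_matrix(activity: ActivityTable, ligands: list[str] | None = None) -> CCCFeatureMatrix:
    """Assemble F from an activity table (optionally restricted to a ligand subset)."""
    if ligands is None:
        ligands = activity.ligands
    if len(ligands) == 0:
        raise ValueError("need at least one ligand to build CCC features")
    pos = {l: i for i, l in enumerate(activity.ligands)}
    try:
        idx = [pos[l] for l in ligands]
    except KeyError as e:
        raise KeyError(f"ligand {e.args[0]!r} not in activity table") from None
    F = np.hstack([activity.send[:, idx], activity.recv[:, idx]])
    return CCCFeatureMatrix(F=F, cell_ids=list(activity.cell_ids), ligands=list(ligands))


@dataclass
class ClusterAssignment:
    labels: np.ndarray
    mode: str
    params: dict


def _standardized_pcs(X: np.ndarray, n_pcs: int, seed: int) -> np.ndarray:
    """log1p -> per-feature z-score -> PCA.

    PC variances are kept (scaling every component to unit variance would
    amplify noise directions to the level of the signal); the block as a whole
    is normalized to unit mean squared norm so that differently sized feature
    spaces are comparable in combined mode.
    """
    X = np.log1p(np.asarray(X, dtype=float))
    mu, sd = X.mean(axis=0), X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd
    rank = int(np.linalg.matrix_rank(Z)) if min(Z.shape) else 0
    k = max(1, min(n_pcs, rank, Z.shape[0] - 1, Z.shape[1]))
    if k < n_pcs:
        logger.warning("reducing n_pcs from %d to %d (matrix rank/size limit)", n_pcs, k)
    P = PCA(n_components=k, random_state=seed).fit_transform(Z)
    scale = np.sqrt((P ** 2).sum(axis=1).mean())
    return P / scale if scale > 0 else P


def _snn_graph(P: np.ndarray, n_neighbors: int) -> sparse.csr_matrix:
    """Shared-nearest-neighbor graph with Jaccard edge weights (Seurat-style)."""
    n = len(P)
    k = min(n_neighbors, n - 1)
    nn = NearestNeighbors(n_neighbors=k).fit(P)
    A = nn.kneighbors_graph(P, mode="connectivity")
    A = A.maximum(A.T)
    shared = (A @ A.T).toarray()
    deg = np.asarray(A.sum(axis=1)).ravel()
    union = deg[:, None] + deg[None, :] - shared
    with np.errstate(divide="ignore", invalid="ignore"):
        J = np.where(union > 0, shared / union, 0.0)
    J[J < 1.0 / 15.0] = 0.0  # prune weak overlaps, Seurat's default cutoff
    np.fill_diagonal(J, 0.0)
    mask = np.asarray(A.maximum(A.T).todense(), dtype=bool)
    J[~mask] = 0.0
    return sparse.csr_matrix(J)


def _community_labels(P: np.ndarray, n_neighbors: int, resolution: float,
                      seed: int) -> np.ndarray:
    """Leiden modularity communities of the SNN graph of the rows of P.

    Duplicate rows — the norm for discrete communication features, where a kNN
    graph would otherwise fragment into per-value components once duplicate
    multiplicity exceeds k — are collapsed to one node each.  Edges between
    unique values are weighted by Jaccard overlap times the product of
    multiplicities, duplicates are tied together by self-loops of weight
    c*(c-1)/2, which makes the partition equivalent to running modularity on
    the fully expanded per-cell graph.
    """
    U, inverse, counts = np.unique(P, axis=0, return_inverse=True, return_counts=True)
    m = len(U)
    if m == 1:
        return np.zeros(len(P), dtype=int)
    J = _snn_graph(U, n_neighbors)
    src, dst = J.nonzero()
    keep = src < dst
    src, dst = src[keep], dst[keep]
    weights = (np.asarray(J[src, dst]).ravel()
               * counts[src] * counts[dst]).tolist()
    edges = list(zip(src.tolist(), dst.tolist()))
    loops = np.nonzero(counts > 1)[0]
    edges += [(int(u), int(u)) for u in loops]
    weights += (counts[loops] * (counts[loops] - 1) / 2.0).tolist()
    g = ig.Graph(n=m, edges=edges)
    part = leidenalg.find_partition(
        g, leidenalg.RBConfigurationVertexPartition,
        weights=weights, resolution_parameter=resolution, seed=seed,
        n_iterations=2,
    )
    membership = np.array(part.membership, dtype=int)
    return membership[inverse]


def cluster_cells(
    F: CCCFeatureMatrix | np.ndarray,
    expr: np.ndarray | None = None,
    mode: str = "ccc_only",
    n_pcs: int = 20,
    resolution: float = 1.0,
    seed: int = 0,
    n_neighbors: int = 15,
    w: float = 1.0,
) -> ClusterAssignment:
    """Cluster cells on CCC features, expression, or both.

    ``expr`` is genes x cells (normalized); required for the expression and
    combined modes.  Combined mode concatenates standardized expression PCs
    with ``w``-scaled standardized CCC-feature PCs.  Deterministic under a
    fixed seed.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}, got {mode!r}")
    Fm = F.F if isinstance(F, CCCFeatureMatrix) else np.asarray(F, dtype=float)
    n_cells = len(Fm)
    params = dict(mode=mode, n_pcs=n_pcs, resolution=resolution, seed=seed,
                  n_neighbors=n_neighbors, w=w)

    if mode == "ccc_only" and np.ptp(Fm) == 0:
        return ClusterAssignment(labels=np.zeros(n_cells, dtype=int), mode=mode, params=params)

    parts = []
    if mode in ("expression_only", "combined"):
        if expr is None:
            raise ValueError(f"mode={mode!r} requires an expression matrix")
        parts.append(_standardized_pcs(np.asarray(expr, dtype=float).T, n_pcs, seed))
    if mode in ("ccc_only", "combined"):
        scale = 1.0 if mode == "ccc_only" else w
        if np.ptp(Fm) == 0:
            parts.append(np.zeros((n_cells, 1)))
        else:
            parts.append(scale * _standardized_pcs(Fm, n_pcs, seed))
    P = np.hstack(parts)

    labels = _community_labels(P, n_neighbors, resolution, seed)
    return ClusterAssignment(labels=labels, mode=mode, params=params)


def compare_clusterings(labels1: np.ndarray, labels2: np.ndarray) -> tuple[float, pd.DataFrame]:
    """Adjusted Rand index plus the cross-tabulation of two labelings."""
    labels1, labels2 = np.asarray(labels1), np.asarray(labels2)
    if labels1.shape != labels2.shape:
        raise ValueError("labelings must cover the same cells")
    ari = float(adjusted_rand_score(labels1, labels2))
    tab = pd.crosstab(pd.Series(labels1, name="labels1"), pd.Series(labels2, name="labels2"))
    return ari, tab
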