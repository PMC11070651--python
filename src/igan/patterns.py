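"""Microenvironment-consistency benchmark: communication matrices, NMF
patterns, and the weighted KL consistency score.

The benchmark compares two views of a tissue: the microenvironment matrix E
(cell types x microenvironment categories, cell counts) and the communication
matrix C (cell types x ligands, mean association load per type pair).  Both
are factorized at the same rank k with non-negative matrix factorization; the
cell-type loadings E^a and C^a are row-normalized to distributions over
patterns and compared with a weighted KL divergence, with cell-type weights
proportional to type abundance and pattern weights taken from the E^b basis
row sums.  NMF pattern order is arbitrary, so C patterns are aligned to E
patterns by the permutation minimizing the total score before comparison.
"""

from __future__ import annotations

import itertools
import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment
from scipy.stats import wilcoxon
from sklearn.cluster import KMeans
from sklearn.decomposition import NMF
from sklearn.exceptions import ConvergenceWarning

from .association import AssociationNetworkSet
from .neighbors import NeighborGraph

logger = logging.getLogger(__name__)

EPS = 1e-12


@dataclass
class CommMatrix:
    """Cell type x ligand communication matrix for one direction."""

    C: np.ndarray
    cell_types: list[str]
    ligands: list[str]
    direction: str  # "sending" | "receiving"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.C, index=pd.Index(self.cell_types, name="cell_type"),
                            columns=self.ligands)


def build_comm_matrix(
    networks: AssociationNetworkSet,
    cell_type: np.ndarray,
    ligands: list[str],
    direction: str = "sending",
) -> CommMatrix:
    """Mean per-pair association load of each ligand, summed over partner types.

    sending:   C[i, j] = sum over types i' != i of the mean (over (i, i') cell
               pairs) of the ligand-j row sum of H^(ab).
    receiving: the same with H^(ba), i.e. blocks whose target type is i.
    Types with no inter-type pairs get a zero row with a warning.
    """
    if direction not in ("sending", "receiving"):
        raise ValueError(f"direction must be 'sending' or 'receiving', got {direction!r}")
    types = sorted(set(np.asarray(cell_type, dtype=object)))
    src_pos = {g: i for i, g in enumerate(networks.source_genes)}
    cols = [src_pos[l] for l in ligands if l in src_pos]
    if len(cols) != len(ligands):
        missing = [l for l in ligands if l not in src_pos]
        logger.warning("ligands %s untested; zero columns", missing)
    C = np.zeros((len(types), len(ligands)))
    tpos = {t: i for i, t in enumerate(types)}
    touched = set()
    for (A, B), block in networks.blocks.items():
        if A == B:
            continue  # inter-type communication only
        mean_load = block.edge_count_matrix() / block.n  # (S, T) summed over pairs
        lig_load = np.zeros(len(ligands))
        present = [li for li, l in enumerate(ligands) if l in src_pos]
        lig_load[present] = mean_load.sum(axis=1)[[src_pos[ligands[li]] for li in present]]
        row = tpos[A] if direction == "sending" else tpos[B]
        C[row] += lig_load
        touched.add(types[row])
    for t in types:
        if t not in touched:
            logger.warning("cell type %r has no inter-type pairs; zero row", t)
    return CommMatrix(C=C, cell_types=types, ligands=list(ligands), direction=direction)


@dataclass
class MicroenvMatrix:
    """Cell type x microenvironment category cell-count matrix."""

    E: np.ndarray
    cell_types: list[str]
    env_labels: np.ndarray  # per-cell microenvironment id

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.E, index=pd.Index(self.cell_types, name="cell_type"),
                            columns=[f"env{j}" for j in range(self.E.shape[1])])


def simple_microenvironments(
    graph: NeighborGraph,
    cell_type: np.ndarray,
    n_env: int,
    seed: int = 0,
) -> MicroenvMatrix:
    """Cluster neighborhood cell-type composition into microenvironment types.

    Each cell is summarized by the cell-type composition of itself plus its
    spatial neighbors; compositions are k-means clustered (fixed seed) into
    ``n_env`` categories and tabulated against cell type.  This is a simple
    composition-clustering stand-in for dedicated microenvironment callers.
    """
    cell_type = np.asarray(cell_type, dtype=object)
    n = graph.n_cells
    if n_env > n:
        raise ValueError(f"n_env={n_env} exceeds the number of cells ({n})")
    types = sorted(set(cell_type))
    tpos = {t: i for i, t in enumerate(types)}
    comp = np.zeros((n, len(types)))
    tidx = np.array([tpos[t] for t in cell_type])
    for a in range(n):
        members = np.append(graph.adjacency[a], a)
        counts = np.bincount(tidx[members], minlength=len(types))
        comp[a] = counts / counts.sum()
    km = KMeans(n_clusters=n_env, random_state=seed, n_init=10)
    env = km.fit_predict(comp)
    E = np.zeros((len(types), n_env))
    for t_i, e_j in zip(tidx, env):
        E[t_i, e_j] += 1
    return MicroenvMatrix(E=E, cell_types=types, env_labels=env)


@dataclass
class PatternDecomposition:
    """NMF factors of a (column-scaled) nonnegative matrix at rank k."""

    W: np.ndarray   # rows x k loadings (E^a / C^a)
    Hb: np.ndarray  # k x cols basis (E^b / C^b)
    rank: int
    seed: int
    reconstruction_error: float
    row_names: list[str]


def nmf_patterns(matrix: np.ndarray | pd.DataFrame, k: int, seed: int = 0,
                 max_iter: int = 5000) -> PatternDecomposition:
    """Multiplicative-update NMF after scaling each column to max 1.

    Mirrors the common communication-pattern workflow: columns on a common
    scale, Frobenius objective, seed-controlled random initialization.
    """
    row_names = list(matrix.index) if isinstance(matrix, pd.DataFrame) else []
    M = np.asarray(matrix, dtype=float)
    if M.min() < 0:
        raise ValueError("matrix must be nonnegative")
    if not M.any():
        raise ValueError("matrix is identically zero; nothing to factorize")
    if k > min(M.shape):
        raise ValueError(f"rank k={k} exceeds matrix dimensions {M.shape}")
    colmax = M.max(axis=0)
    scaled = np.divide(M, colmax, out=np.zeros_like(M), where=colmax > 0)
    model = NMF(n_components=k, init="random", solver="mu", beta_loss="frobenius",
                max_iter=max_iter, random_state=seed, tol=1e-7)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        W = model.fit_transform(scaled)
    return PatternDecomposition(W=W, Hb=model.components_, rank=k, seed=seed,
                                reconstruction_error=float(model.reconstruction_err_),
                                row_names=row_names or [str(i) for i in range(M.shape[0])])


def rank_scan(matrix: np.ndarray | pd.DataFrame, ks, seed: int = 0) -> pd.DataFrame:
    """Reconstruction error across candidate ranks (the elbow informs the choice of k)."""
    rows = [(int(k), nmf_patterns(matrix, int(k), seed=seed).reconstruction_error)
            for k in ks]
    return pd.DataFrame(rows, columns=["k", "reconstruction_error"])


@dataclass
class ConsistencyScore:
    value: float
    per_type: pd.DataFrame
    w_celltype: np.ndarray
    w_pattern: np.ndarray
    permutation: tuple[int, ...]


def _normalize_rows(A: np.ndarray) -> np.ndarray:
    P = np.clip(np.asarray(A, dtype=float), EPS, None)
    return P / P.sum(axis=1, keepdims=True)


def _alignment_costs(P: np.ndarray, Q: np.ndarray, wc: np.ndarray, wp: np.ndarray) -> np.ndarray:
    """cost[j, j'] = contribution of matching E-pattern j with C-pattern j'."""
    k = P.shape[1]
    cost = np.empty((k, k))
    for j in range(k):
        term = wc[:, None] * wp[j] * P[:, j:j + 1] * np.log(P[:, j:j + 1] / Q)
        cost[j] = term.sum(axis=0)
    return cost


def weighted_kl(
    decompE: PatternDecomposition,
    decompC: PatternDecomposition,
    cell_counts: np.ndarray,
) -> ConsistencyScore:
    """Weighted KL divergence between aligned pattern loadings.

    KL_w = sum_ij W_celltype^i * W_pattern^j * Ea_ij * log(Ea_ij / Ca_ij)
    with W_celltype the cell-type proportions, W_pattern the E^b row sums,
    Ea/Ca the row-normalized loadings (floored at 1e-12), and the C patterns
    permuted to minimize the total (assignment-optimal alignment; the score is
    therefore invariant to any column permutation of the C decomposition).
    """
    if decompE.rank != decompC.rank:
        raise ValueError(f"rank mismatch: {decompE.rank} vs {decompC.rank}")
    if decompE.W.shape[0] != decompC.W.shape[0]:
        raise ValueError("decompositions cover different numbers of cell types")
    k = decompE.rank
    cell_counts = np.asarray(cell_counts, dtype=float)
    wc = cell_counts / cell_counts.sum()
    wp = decompE.Hb.sum(axis=1)
    P = _normalize_rows(decompE.W)
    Q = _normalize_rows(decompC.W)
    cost = _alignment_costs(P, Q, wc, wp)
    if k <= 8:
        best_perm, best = None, np.inf
        for perm in itertools.permutations(range(k)):
            tot = cost[np.arange(k), perm].sum()
            if tot < best:
                best, best_perm = tot, perm
        perm = tuple(best_perm)
    else:
        rows, cols = linear_sum_assignment(cost)
        perm = tuple(int(c) for c in cols[np.argsort(rows)])
    Qp = Q[:, list(perm)]
    contrib = wc[:, None] * wp[None, :] * P * np.log(P / Qp)
    per_type = pd.DataFrame(contrib, index=decompE.row_names,
                            columns=[f"pattern{j}" for j in range(k)])
    return ConsistencyScore(value=float(contrib.sum()), per_type=per_type,
                            w_celltype=wc, w_pattern=wp, permutation=perm)


def benchmark(
    env_decomps: list[PatternDecomposition],
    cell_counts: list[np.ndarray],
    method_comms: dict[str, list[PatternDecomposition]],
    min_paired: int = 5,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score several methods' communication patterns against microenvironments.

    ``env_decomps[d]`` and each method's ``decomps[d]`` refer to the same
    dataset d.  Returns a per-(method, dataset) KL_w table and paired
    Wilcoxon signed-rank comparisons between methods (skipped, p = NaN, with
    fewer than ``min_paired`` paired scores; identical score vectors give
    p = 1 by convention).
    """
    rows = []
    for name, decomps in method_comms.items():
        if len(decomps) != len(env_decomps):
            raise ValueError(f"method {name!r} has {len(decomps)} decompositions "
                             f"for {len(env_decomps)} datasets")
        for d, (de, dc) in enumerate(zip(env_decomps, decomps)):
            score = weighted_kl(de, dc, cell_counts[d])
            rows.append((name, d, score.value))
    scores = pd.DataFrame(rows, columns=["method", "dataset", "kl_w"])

    tests = []
    names = sorted(method_comms)
    for i, m1 in enumerate(names):
        for m2 in names[i + 1:]:
            s1 = scores.loc[scores["method"] == m1].sort_values("dataset")["kl_w"].to_numpy()
            s2 = scores.loc[scores["method"] == m2].sort_values("dataset")["kl_w"].to_numpy()
            if len(s1) < min_paired:
                p = np.nan
            elif np.allclose(s1, s2):
                p = 1.0
            else:
                p = float(wilcoxon(s1, s2, zero_method="wilcox").pvalue)
            tests.append((m1, m2, p))
    return scores, pd.DataFrame(tests, columns=["method1", "method2", "wilcoxon_p"])


def shuffle_rows(C: CommMatrix, seed: int = 0) -> CommMatrix:
    """Row-permuted control: breaks the cell-type correspondence of C."""
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(C.cell_types))
    while len(perm) > 1 and (perm == np.arange(len(perm))).all():
        perm = rng.permutation(len(perm))
    return CommMatrix(C=C.C[perm], cell_types=C.cell_types, ligands=C.ligands,
                      direction=C.direction)
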