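"""The intercellular gene-association statistic and per-pair network construction.

For a directed cell-type pair (A, B) with n adjacent cell pairs (a_k, b_k),
the scatter of gene x (measured in the a-cells) against gene y (in the
b-cells) is tested for dependence pair by pair, in the style of cell-specific
networks: around each focal pair k we take the ceil(b*n) pairs whose x-values
are nearest to x_k (the x-window) and likewise for y, and compare the joint
window occupancy n_xy with what independence predicts from the marginal
occupancies n_x and n_y.

The classical standardized statistic is

    rho_k = (n_xy/n - (n_x/n)(n_y/n)) / sqrt(n_x n_y (n-n_x)(n-n_y) / (n^4 (n-1)))

which is approximately standard normal under independence for large windows.
Because the focal pair is counted in both windows, however, the exact null law
of the joint count is n_xy - 1 ~ Hypergeometric(n-1, n_x-1, n_y-1), whose mean
1 + (n_x-1)(n_y-1)/(n-1) exceeds n_x n_y / n by almost one pair; thresholding
rho_k at the normal quantile therefore over-rejects by several-fold at typical
window sizes.  The default decision rule (``null="exact"``) uses the exact
hypergeometric tail and keeps the test at or below its nominal level;
``null="normal"`` selects the plain rho-threshold rule.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import sparse
from scipy.stats import hypergeom, norm

from .io import SpatialDataset, normalize
from .neighbors import CellPairSet

logger = logging.getLogger(__name__)


class TooFewPairsError(ValueError):
    """The scatter has fewer pairs than the test requires (n >= 3)."""


@dataclass
class PairScatter:
    """Expression of gene x in a_1..a_n against gene y in b_1..b_n."""

    x: np.ndarray
    y: np.ndarray

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.shape != self.y.shape or self.x.ndim != 1:
            raise ValueError("x and y must be 1-D arrays of equal length")

    @property
    def n(self) -> int:
        return len(self.x)


@dataclass
class NeighborhoodCounts:
    """Window occupancies around focal pair k (k counted in all three)."""

    k: int
    n_x: int
    n_y: int
    n_xy: int


def window_size(n: int, b: float) -> int:
    if not 0 < b < 1:
        raise ValueError(f"window fraction must be in (0,1), got {b}")
    return int(math.ceil(b * n))


def _window_matrix(values: np.ndarray, w: int) -> np.ndarray:
    """Boolean (n, n) matrix; row k flags the w values nearest to values[k].

    Ties are broken by pair index (stable sort); the focal pair is always a
    member of its own window, displacing the farthest selected pair if needed.
    """
    v = np.asarray(values, dtype=float)
    n = len(v)
    order = np.argsort(np.abs(v[None, :] - v[:, None]), axis=1, kind="stable")
    sel = order[:, :w]
    W = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), w)
    W[rows, sel.ravel()] = True
    diag = np.arange(n)
    missing = ~W[diag, diag]
    if missing.any():
        idx = diag[missing]
        W[idx, sel[idx, w - 1]] = False
        W[idx, idx] = True
    return W


def window_counts(scatter: PairScatter, k: int, b: float) -> NeighborhoodCounts:
    """Marginal and joint window occupancies for focal pair k."""
    n = scatter.n
    if n < 3:
        raise TooFewPairsError(f"need at least 3 pairs, got {n}")
    if not 0 <= k < n:
        raise IndexError(f"focal index {k} out of range for n={n}")
    w = window_size(n, b)
    Wx = _window_matrix(scatter.x, w)[k]
    Wy = _window_matrix(scatter.y, w)[k]
    return NeighborhoodCounts(k=k, n_x=int(Wx.sum()), n_y=int(Wy.sum()),
                              n_xy=int((Wx & Wy).sum()))


def association_statistic(counts: NeighborhoodCounts, n: int) -> float:
    """Standardized window co-occupancy statistic rho_k.

    Returns NaN (degenerate: no information) when a marginal window is empty
    or spans all pairs.
    """
    nx, ny, nxy = counts.n_x, counts.n_y, counts.n_xy
    if nx in (0, n) or ny in (0, n):
        return float("nan")
    num = nxy / n - (nx / n) * (ny / n)
    den = math.sqrt(nx * ny * (n - nx) * (n - ny) / (n ** 4 * (n - 1)))
    return num / den


def critical_joint_count(n: int, n_x: int, n_y: int, alpha: float, null: str = "exact") -> int:
    """Smallest joint count c such that n_xy >= c rejects independence at level alpha.

    exact:  smallest c with P(1 + Hypergeom(n-1, n_x-1, n_y-1) >= c) <= alpha.
    normal: smallest integer c with rho(c) > PhiInv(1 - alpha).
    Returns n + 1 (unattainable) when no count rejects.
    """
    if not 0 < alpha < 1:
        raise ValueError(f"alpha must be in (0,1), got {alpha}")
    if n_x in (0, n) or n_y in (0, n):
        return n + 1
    if null == "normal":
        z = norm.ppf(1 - alpha)
        den = math.sqrt(n_x * n_y * (n - n_x) * (n - n_y) / (n ** 4 * (n - 1)))
        bound = n * ((n_x / n) * (n_y / n) + z * den)
        c = int(math.floor(bound)) + 1
        return c if c <= n else n + 1
    if null != "exact":
        raise ValueError(f"null must be 'exact' or 'normal', got {null!r}")
    smax = min(n_x, n_y) - 1
    s = np.arange(smax + 2)  # candidate S thresholds 0..smax+1
    sf = hypergeom.sf(s - 1, n - 1, n_x - 1, n_y - 1)  # P(S >= s)
    ok = np.nonzero(sf <= alpha)[0]
    if len(ok) == 0 or ok[0] > smax:
        return n + 1
    return int(ok[0]) + 1  # n_xy = S + 1


def test_gene_pair(
    scatter: PairScatter,
    b: float = 0.1,
    alpha: float = 0.01,
    null: str = "exact",
    alternative: str = "greater",
) -> np.ndarray:
    """Per-pair binary association vector h (length n) for one gene pair.

    One-sided test for positive association by default.  Constant marginals
    (zero spread in x or y across the pairs) carry no dependence information
    and yield all zeros.
    """
    n = scatter.n
    if n < 3:
        raise TooFewPairsError(f"need at least 3 pairs, got {n}")
    if np.ptp(scatter.x) == 0 or np.ptp(scatter.y) == 0:
        return np.zeros(n, dtype=np.uint8)
    w = window_size(n, b)
    Wx = _window_matrix(scatter.x, w)
    Wy = _window_matrix(scatter.y, w)
    nxy = (Wx & Wy).sum(axis=1)
    if alternative == "greater":
        crit = critical_joint_count(n, w, w, alpha, null)
        h = nxy >= crit
    elif alternative == "two-sided":
        crit_hi = critical_joint_count(n, w, w, alpha / 2, null)
        if null == "normal":
            z = norm.ppf(1 - alpha / 2)
            den = math.sqrt(w * w * (n - w) * (n - w) / (n ** 4 * (n - 1)))
            lo = n * ((w / n) ** 2 - z * den)
            crit_lo = int(math.ceil(lo)) - 1
        else:
            s = np.arange(min(w, n) + 1)
            cdf = hypergeom.cdf(s, n - 1, w - 1, w - 1)
            ok = np.nonzero(cdf <= alpha / 2)[0]
            crit_lo = int(ok[-1]) + 1 if len(ok) else -1
        h = (nxy >= crit_hi) | (nxy <= crit_lo)
    else:
        raise ValueError(f"alternative must be 'greater' or 'two-sided', got {alternative!r}")
    return h.astype(np.uint8)


# --------------------------------------------------------------------------
# network containers


@dataclass
class NetworkBlock:
    """Per-pair association networks for one ordered cell-type pair (A, B).

    H is stored as a sparse (n_pairs, S*T) matrix; row k, flattened over
    (source gene i, target gene j), is the binary network H^(a_k b_k).
    """

    source_type: str
    target_type: str
    a: np.ndarray
    b: np.ndarray
    H: sparse.csr_matrix
    n_source: int
    n_target: int

    @property
    def n(self) -> int:
        return len(self.a)

    def pair_network(self, k: int) -> sparse.csr_matrix:
        """H^(a_k b_k) as a sparse (S, T) matrix (directional, not symmetric)."""
        row = self.H.getrow(k).toarray().ravel()
        return sparse.csr_matrix(row.reshape(self.n_source, self.n_target))

    def source_rowsums(self) -> np.ndarray:
        """(n_pairs, S) array: sum_j H_ij per pair, per source gene."""
        S, T = self.n_source, self.n_target
        M = sparse.kron(sparse.eye(S, format="csr"), np.ones((T, 1)))
        return np.asarray((self.H @ M).todense())

    def edge_count_matrix(self) -> np.ndarray:
        """(S, T) matrix of sum_k H_ij over the block's pairs."""
        return np.asarray(self.H.sum(axis=0)).reshape(self.n_source, self.n_target)


@dataclass
class AssociationNetworkSet:
    """All per-pair networks across ordered type pairs, plus test parameters."""

    source_genes: list[str]
    target_genes: list[str]
    blocks: dict[tuple[str, str], NetworkBlock]
    params: dict = field(default_factory=dict)
    skipped: dict[tuple[str, str], int] = field(default_factory=dict)

    def source_index(self, gene: str) -> int:
        return self.source_genes.index(gene)

    def total_edges(self) -> int:
        return int(sum(b.H.sum() for b in self.blocks.values()))


def expressed_genes(ds: SpatialDataset, min_cells_frac: float = 0.05) -> list[str]:
    """Genes detected in at least ``min_cells_frac`` of cells (on raw or current values)."""
    X = ds.raw if ds.raw is not None else ds.expr
    X = np.asarray(X.todense()) if sparse.issparse(X) else np.asarray(X)
    frac = (X > 0).mean(axis=1)
    return [g for g, f in zip(ds.gene_ids, frac) if f >= min_cells_frac]


def _window_index_stack(values: np.ndarray, w: int) -> tuple[np.ndarray, np.ndarray]:
    """Window member indices (G, n, w) and degeneracy mask for a gene x pairs value matrix."""
    G, n = values.shape
    idx = np.empty((G, n, w), dtype=np.int32)
    degenerate = np.ptp(values, axis=1) == 0
    for g in range(G):
        if degenerate[g]:
            idx[g] = 0
            continue
        v = values[g]
        order = np.argsort(np.abs(v[None, :] - v[:, None]), axis=1, kind="stable")
        sel = order[:, :w].copy()
        has_focal = (sel == np.arange(n)[:, None]).any(axis=1)
        if not has_focal.all():
            rows = np.nonzero(~has_focal)[0]
            sel[rows, w - 1] = rows
        idx[g] = sel
    return idx, degenerate


def build_networks(
    dataset: SpatialDataset,
    pairs: CellPairSet | dict[tuple[str, str], CellPairSet] | list[CellPairSet],
    source_genes: list[str],
    target_genes: list[str],
    b: float = 0.1,
    alpha: float = 0.01,
    min_pairs: int = 10,
    null: str = "exact",
) -> AssociationNetworkSet:
    """Run the pairwise association test for every (source, target) gene pair.

    The test runs on normalized expression; raw-count datasets are normalized
    on the fly.  Pair sets with fewer than ``min_pairs`` pairs are skipped with
    a warning and recorded in ``skipped``.
    """
    if not source_genes or not target_genes:
        raise ValueError("source and target gene lists must be non-empty")
    ds = dataset if dataset.normalized else normalize(dataset)
    src_rows = ds.gene_index(list(source_genes))
    tgt_rows = ds.gene_index(list(target_genes))
    X = ds.expr_dense()

    if isinstance(pairs, CellPairSet):
        pair_sets = {(pairs.source_type, pairs.target_type): pairs}
    elif isinstance(pairs, list):
        pair_sets = {(p.source_type, p.target_type): p for p in pairs}
    else:
        pair_sets = dict(pairs)

    S, T = len(src_rows), len(tgt_rows)
    blocks: dict[tuple[str, str], NetworkBlock] = {}
    skipped: dict[tuple[str, str], int] = {}
    for key, ps in sorted(pair_sets.items()):
        n = ps.n
        if n < min_pairs:
            logger.warning("type pair %s skipped: %d pairs < min_pairs=%d", key, n, min_pairs)
            skipped[key] = n
            continue
        w = window_size(n, b)
        crit = critical_joint_count(n, w, w, alpha, null)
        xs = X[np.ix_(src_rows, ps.a)]  # (S, n)
        ys = X[np.ix_(tgt_rows, ps.b)]  # (T, n)
        Wy_idx, y_degen = _window_index_stack(ys, w)
        rows3 = np.arange(n)[None, :, None]
        h = np.zeros((S, T, n), dtype=np.uint8)
        if crit <= n:
            for si in range(S):
                xv = xs[si]
                if np.ptp(xv) == 0:
                    continue
                Wx = _window_matrix(xv, w)
                nxy = Wx[rows3, Wy_idx].sum(axis=2)  # (T, n)
                hit = nxy >= crit
                hit[y_degen, :] = False
                h[si] = hit.astype(np.uint8)
        Hmat = sparse.csr_matrix(h.transpose(2, 0, 1).reshape(n, S * T))
        blocks[key] = NetworkBlock(
            source_type=key[0], target_type=key[1], a=ps.a.copy(), b=ps.b.copy(),
            H=Hmat, n_source=S, n_target=T,
        )
    params = dict(b=b, alpha=alpha, min_pairs=min_pairs, null=null,
                  source_genes=list(source_genes), target_genes=list(target_genes))
    return AssociationNetworkSet(
        source_genes=list(source_genes), target_genes=list(target_genes),
        blocks=blocks, params=params, skipped=skipped,
    )


# --------------------------------------------------------------------------
# flat-file round trip (sparse triplets CSV + JSON metadata sidecar)


def write_networks(nets: AssociationNetworkSet, path) -> None:
    """Write networks as sparse triplets CSV plus a ``<path>.meta.json`` sidecar.

    The CSV holds one row per association (block, pair index, cell indices,
    gene names); the sidecar records gene lists, parameters and the full pair
    lists so that blocks with no associations survive the round trip.
    """
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    rows = []
    for (A, B), block in sorted(nets.blocks.items()):
        coo = block.H.tocoo()
        for k, flat, val in zip(coo.row, coo.col, coo.data):
            if not val:
                continue
            i, j = divmod(int(flat), block.n_target)
            rows.append((A, B, int(k), int(block.a[k]), int(block.b[k]),
                         nets.source_genes[i], nets.target_genes[j]))
    df = pd.DataFrame(rows, columns=["source_type", "target_type", "pair_index",
                                     "cell_a", "cell_b", "gene_i", "gene_j"])
    df.to_csv(path, index=False)
    meta = {
        "source_genes": nets.source_genes,
        "target_genes": nets.target_genes,
        "params": nets.params,
        "skipped": [[list(k), v] for k, v in sorted(nets.skipped.items())],
        "blocks": [
            {"source_type": A, "target_type": B,
             "a": block.a.astype(int).tolist(), "b": block.b.astype(int).tolist()}
            for (A, B), block in sorted(nets.blocks.items())
        ],
    }
    Path(str(path) + ".meta.json").write_text(json.dumps(meta, sort_keys=True) + "\n")


def read_networks(path) -> AssociationNetworkSet:
    """Inverse of :func:`write_networks`."""
    import json
    from pathlib import Path

    import pandas as pd

    path = Path(path)
    meta = json.loads(Path(str(path) + ".meta.json").read_text())
    df = pd.read_csv(path)
    src = meta["source_genes"]
    tgt = meta["target_genes"]
    spos = {g: i for i, g in enumerate(src)}
    tpos = {g: i for i, g in enumerate(tgt)}
    S, T = len(src), len(tgt)
    blocks: dict[tuple[str, str], NetworkBlock] = {}
    for binfo in meta["blocks"]:
        A, B = binfo["source_type"], binfo["target_type"]
        a = np.array(binfo["a"], dtype=int)
        bb = np.array(binfo["b"], dtype=int)
        sub = df[(df["source_type"] == A) & (df["target_type"] == B)]
        k_idx = sub["pair_index"].to_numpy(dtype=int)
        flat = (sub["gene_i"].map(spos).to_numpy(dtype=int) * T
                + sub["gene_j"].map(tpos).to_numpy(dtype=int))
        H = sparse.csr_matrix(
            (np.ones(len(sub), dtype=np.uint8), (k_idx, flat)),
            shape=(len(a), S * T),
        )
        blocks[(A, B)] = NetworkBlock(source_type=A, target_type=B, a=a, b=bb,
                                      H=H, n_source=S, n_target=T)
    skipped = {tuple(k): v for k, v in meta.get("skipped", [])}
    return AssociationNetworkSet(source_genes=src, target_genes=tgt, blocks=blocks,
                                 params=meta.get("params", {}), skipped=skipped)
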