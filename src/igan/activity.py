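"""Per-cell, per-ligand communication activity aggregated from the networks.

A cell a with t_a spatial neighbors sends signal on ligand i at rate
(sum over its t_a outgoing networks of the ligand-i row sum of H) / t_a, and
receives at the analogous rate over incoming networks H^(b_k a).  Overall CCC
strength of a cell is the sum of sending and receiving activity over all
ligands.  Cells with t_a = 0 have zero activity by convention; neighbors whose
type-pair block was skipped (too few pairs) contribute nothing but still count
in t_a, which keeps t_a a purely spatial quantity.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.stats.multitest import multipletests

from .association import AssociationNetworkSet
from .neighbors import NeighborGraph

logger = logging.getLogger(__name__)


@dataclass
class ActivityTable:
    """send/recv are (n_cells, n_ligands); strength their row-sum total."""

    cell_ids: list[str]
    ligands: list[str]
    send: np.ndarray
    recv: np.ndarray
    t: np.ndarray

    @property
    def strength(self) -> np.ndarray:
        return self.send.sum(axis=1) + self.recv.sum(axis=1)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(
            np.hstack([self.send, self.recv]),
            index=pd.Index(self.cell_ids, name="cell_id"),
            columns=[f"send:{l}" for l in self.ligands] + [f"recv:{l}" for l in self.ligands],
        )
        df["strength"] = self.strength
        df["t"] = self.t
        return df


def compute_activity(
    networks: AssociationNetworkSet,
    graph: NeighborGraph,
    ligands: list[str],
    cell_ids: list[str] | None = None,
) -> ActivityTable:
    """Aggregate per-pair networks into per-cell sending/receiving activity.

    ``ligands`` must index into the networks' source genes; ligands that were
    not tested get zero activity with a warning.
    """
    n_cells = graph.n_cells
    if cell_ids is None:
        cell_ids = [str(i) for i in range(n_cells)]
    L = len(ligands)
    src_pos = {g: i for i, g in enumerate(networks.source_genes)}
    cols = np.full(L, -1, dtype=int)
    for li, lig in enumerate(ligands):
        if lig in src_pos:
            cols[li] = src_pos[lig]
        else:
            logger.warning("ligand %r absent from tested source genes; activity set to 0", lig)

    send_raw = np.zeros((n_cells, L))
    recv_raw = np.zeros((n_cells, L))
    present = cols >= 0
    for block in networks.blocks.values():
        rowsums = block.source_rowsums()  # (n_pairs, S)
        lig_sums = np.zeros((block.n, L))
        lig_sums[:, present] = rowsums[:, cols[present]]
        np.add.at(send_raw, block.a, lig_sums)
        np.add.at(recv_raw, block.b, lig_sums)

    t = graph.t.astype(float)
    scale = np.where(t > 0, t, 1.0)
    send = send_raw / scale[:, None]
    recv = recv_raw / scale[:, None]
    send[t == 0] = 0.0
    recv[t == 0] = 0.0
    return ActivityTable(cell_ids=list(cell_ids), ligands=list(ligands),
                         send=send, recv=recv, t=graph.t)


def strength_map(activity: ActivityTable, coords: np.ndarray) -> pd.DataFrame:
    """Per-cell CCC strength as a plottable scalar field (with a log1p column)."""
    coords = np.asarray(coords, dtype=float)
    s = activity.strength
    return pd.DataFrame({
        "cell_id": activity.cell_ids,
        "x": coords[:, 0],
        "y": coords[:, 1],
        "strength": s,
        "log1p_strength": np.log1p(s),
    })


def region_ligand_test(
    activity: ActivityTable,
    region_labels: np.ndarray,
    min_cells: int = 3,
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """Per-ligand rank-sum comparison of send/recv activity between two regions.

    Returns a tidy frame (ligand, direction, statistic, p, q, significant) with
    BH-adjusted q-values per direction.  Ligands with identically zero activity
    in a direction are excluded from that direction's testing.
    """
    labels = np.asarray(region_labels)
    regions = sorted(pd.unique(labels).tolist())
    if len(regions) != 2:
        raise ValueError(f"need exactly two region labels, got {regions}")
    m0, m1 = labels == regions[0], labels == regions[1]
    if m0.sum() < min_cells or m1.sum() < min_cells:
        raise ValueError(f"each region needs >= {min_cells} cells")

    rows = []
    for direction, mat in (("send", activity.send), ("recv", activity.recv)):
        for li, lig in enumerate(activity.ligands):
            v = mat[:, li]
            if not v.any():
                continue
            a, bvals = v[m0], v[m1]
            if np.ptp(v) == 0:
                stat, p = np.nan, 1.0
            else:
                stat, p = mannwhitneyu(a, bvals, alternative="two-sided")
            rows.append((lig, direction, float(stat), float(p)))
    df = pd.DataFrame(rows, columns=["ligand", "direction", "statistic", "p"])
    if df.empty:
        df["q"] = df["significant"] = []
        return df
    qs = np.empty(len(df))
    for direction in df["direction"].unique():
        m = df["direction"] == direction
        qs[m.to_numpy()] = multipletests(df.loc[m, "p"], method="fdr_bh")[1]
    df["q"] = qs
    df["significant"] = df["q"] < q_threshold
    return df


def select_high_activity_ligands(
    activity: ActivityTable,
    cell_mask: np.ndarray | None = None,
    top: int = 10,
) -> list[str]:
    """Top ligands by mean total (send + recv) activity over the given cells.

    At most ``top`` ligands, restricted to those with strictly positive mean
    activity, ordered by decreasing activity (ties by ligand name).
    """
    total = activity.send + activity.recv
    if cell_mask is not None:
        total = total[np.asarray(cell_mask)]
    mean = total.mean(axis=0) if len(total) else np.zeros(len(activity.ligands))
    order = sorted(range(len(activity.ligands)), key=lambda i: (-mean[i], activity.ligands[i]))
    return [activity.ligands[i] for i in order[:top] if mean[i] > 0]
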