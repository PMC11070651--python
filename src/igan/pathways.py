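"""Downstream-gene selection, enrichment, and the cell-interaction-pathway graph.

For a directed cell-type pair, the downstream genes of a ligand are the target
genes associated with it in more than a fixed fraction (default 1%) of the
N tested cell pairs.  Pathway membership of those genes is scored by one-sided
hypergeometric over-representation with Benjamini-Hochberg correction, and a
pathway enters the Sankey graph only when it is both enriched and contains at
least one subunit of a receptor cognate to the ligand.  The four node tiers
are: ligand-ontology terms, ligands, receptor units, pathways.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .activity import ActivityTable, select_high_activity_ligands
from .association import AssociationNetworkSet
from .io import GeneSetCollection, LigandReceptorDB

logger = logging.getLogger(__name__)


def select_downstream_genes(
    networks: AssociationNetworkSet,
    source_type: str,
    target_type: str,
    ligand: str,
    frac: float = 0.01,
) -> set[str]:
    """Target genes associated with ``ligand`` in more than frac*N of the pairs.

    N is the number of tested (source_type, target_type) cell pairs; the
    threshold is strict (count > frac*N).  Empty when the type pair was
    skipped or the ligand untested.
    """
    key = (source_type, target_type)
    if key not in networks.blocks:
        return set()
    block = networks.blocks[key]
    if ligand not in networks.source_genes:
        return set()
    i = networks.source_genes.index(ligand)
    counts = block.edge_count_matrix()[i]  # (T,)
    thresh = frac * block.n
    return {g for g, c in zip(networks.target_genes, counts) if c > thresh}


def enrich(
    query: set[str] | list[str],
    collection: GeneSetCollection,
    universe: set[str] | list[str],
    q_threshold: float = 0.05,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation of ``query`` in each gene set.

    Sets are restricted to the universe before testing.  Returns a frame with
    columns (set, overlap, set_size, universe_size, query_size, p, q,
    significant), BH-corrected across the collection's sets.
    """
    universe = set(universe)
    query = set(query) & universe
    if not universe >= query:
        raise ValueError("universe must contain the query")
    rows = []
    U, q_n = len(universe), len(query)
    for name, genes in sorted(collection.items()):
        gs = genes & universe
        K = len(gs)
        if K == 0:
            continue
        ov = len(gs & query)
        p = float(hypergeom.sf(ov - 1, U, K, q_n)) if q_n else 1.0
        rows.append((name, ov, K, U, q_n, min(p, 1.0)))
    df = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "universe_size",
                                     "query_size", "p"])
    if df.empty:
        df["q"] = df["significant"] = []
        return df
    df["q"] = multipletests(df["p"], method="fdr_bh")[1]
    df["significant"] = df["q"] < q_threshold
    return df.sort_values(["q", "p", "set"]).reset_index(drop=True)


@dataclass
class SankeyGraph:
    """Four-tier weighted flow graph: ontology -> ligand -> receptor -> pathway.

    Links from receptor units to pathways are per (ligand, receptor, pathway)
    and weighted by the number of that ligand's downstream target genes inside
    the pathway; membership/cognate links in the earlier tiers have weight 1.
    """

    nodes: list[dict] = field(default_factory=list)   # {name, tier}
    links: list[dict] = field(default_factory=list)   # {source, target, weight, ligand}

    def node_names(self, tier: int) -> list[str]:
        return [n["name"] for n in self.nodes if n["tier"] == tier]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = json.dumps({"nodes": self.nodes, "links": self.links},
                             indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(payload + "\n")
        return payload

    def links_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.links, columns=["source", "target", "weight", "ligand"])

    @property
    def empty(self) -> bool:
        return not self.links and not self.nodes


def build_sankey(
    activity: ActivityTable,
    networks: AssociationNetworkSet,
    lr_db: LigandReceptorDB,
    pathway_sets: GeneSetCollection,
    ontology_sets: GeneSetCollection | None,
    source_type: str,
    target_type: str,
    top_ligands: int = 10,
    frac: float = 0.01,
    q_threshold: float = 0.05,
    cell_mask: np.ndarray | None = None,
) -> SankeyGraph:
    """Assemble the panoramic cell-interaction-pathway graph for (A, B).

    Tier 2 holds the high-activity ligands (top by mean activity) that are in
    the ligand-receptor database and have a non-empty downstream gene set;
    tier 3 their receptor units; tier 4 the pathways that are enriched in a
    ligand's downstream genes AND contain a subunit of one of its receptors.
    Tier 1 holds ontology terms enriched in the selected ligand list.
    """
    selected = select_high_activity_ligands(activity, cell_mask=cell_mask, top=top_ligands)
    selected = [l for l in selected if l in set(lr_db.ligands)]
    if not selected:
        logger.warning("no high-activity ligand found in the LR database; empty graph")
        return SankeyGraph()

    universe = set(networks.target_genes)
    nodes: list[dict] = []
    links: list[dict] = []
    kept_ligands: list[str] = []
    kept_receptors: list[str] = []
    kept_pathways: list[str] = []

    for lig in selected:
        downstream = select_downstream_genes(networks, source_type, target_type, lig, frac=frac)
        if not downstream:
            logger.info("ligand %s has no downstream genes above the count threshold", lig)
            continue
        enr = enrich(downstream, pathway_sets, universe, q_threshold=q_threshold)
        enriched = set(enr.loc[enr["significant"], "set"]) if not enr.empty else set()
        units = lr_db.units_for(lig)
        lig_has_link = False
        for receptor, subunits in units:
            for pw in sorted(enriched):
                pw_genes = pathway_sets[pw]
                if not pw_genes & set(subunits):
                    continue  # receptor filter: pathway must contain a cognate subunit
                weight = len(downstream & pw_genes)
                if weight < 1:
                    continue
                links.append({"source": receptor, "target": pw, "weight": int(weight),
                              "ligand": lig})
                lig_has_link = True
                if pw not in kept_pathways:
                    kept_pathways.append(pw)
                if receptor not in kept_receptors:
                    kept_receptors.append(receptor)
        if lig_has_link or units:
            kept_ligands.append(lig)
            for receptor, _ in units:
                links.append({"source": lig, "target": receptor, "weight": 1, "ligand": lig})
                if receptor not in kept_receptors:
                    kept_receptors.append(receptor)

    if not kept_ligands:
        logger.warning("no ligand passed downstream-gene selection; empty graph")
        return SankeyGraph()

    if ontology_sets is not None and len(ontology_sets):
        ont = enrich(set(kept_ligands), ontology_sets, set(lr_db.ligands),
                     q_threshold=q_threshold)
        for term in ont.loc[ont["significant"], "set"]:
            members = ontology_sets[term] & set(kept_ligands)
            for lig in sorted(members):
                links.append({"source": term, "target": lig, "weight": 1, "ligand": lig})
            nodes.append({"name": term, "tier": 1})

    nodes += [{"name": l, "tier": 2} for l in kept_ligands]
    nodes += [{"name": r, "tier": 3} for r in kept_receptors]
    nodes += [{"name": p, "tier": 4} for p in kept_pathways]
    return SankeyGraph(nodes=nodes, links=links)


def plot_sankey(graph: SankeyGraph, path: str | Path) -> None:
    """Minimal static rendering: four node columns with weighted connecting lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(9, 6))
    pos: dict[str, tuple[float, float]] = {}
    for tier in (1, 2, 3, 4):
        names = graph.node_names(tier)
        for i, name in enumerate(names):
            y = 1 - (i + 0.5) / max(len(names), 1)
            pos[name] = (tier, y)
            ax.text(tier, y, name, ha="center", va="center", fontsize=8,
                    bbox=dict(boxstyle="round", fc="#eef", ec="#88a"))
    wmax = max((l["weight"] for l in graph.links), default=1)
    for link in graph.links:
        if link["source"] in pos and link["target"] in pos:
            (x0, y0), (x1, y1) = pos[link["source"]], pos[link["target"]]
            ax.plot([x0, x1], [y0, y1], color="#779", alpha=0.6,
                    lw=0.5 + 3.0 * link["weight"] / wmax, zorder=0)
    ax.set_xlim(0.5, 4.5)
    ax.set_xticks([1, 2, 3, 4])
    ax.set_xticklabels(["ontology", "ligand", "receptor", "pathway"])
    ax.set_yticks([])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
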