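"""Readers, writers and containers for the external formats the pipeline touches.

Expression comes in either as a Matrix Market triplet file with plain-text
gene/cell ID sidecars, or as a dense CSV with one row per gene.  Coordinates
and cell-type labels are CSV.  Ligand-receptor interactions use a
CellChatDB-like CSV layout (``ligand,receptor,pathway`` with ``_``-joined
receptor subunits), and gene sets use standard GMT.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import io as spio
from scipy import sparse

logger = logging.getLogger(__name__)

PLATFORMS = ("bead", "grid10x")


class DataError(ValueError):
    """Malformed or inconsistent input data."""


@dataclass
class SpatialDataset:
    """Expression + coordinates (+ optional labels) for one slide.

    ``expr`` is genes x cells, dense or scipy sparse, non-negative.  ``coords``
    is cells x 2 in whatever length unit the platform reports.  ``normalized``
    records whether ``expr`` holds library-size-scaled log1p values; the raw
    counts are kept in ``raw`` after :func:`normalize`.
    """

    expr: np.ndarray | sparse.spmatrix
    gene_ids: list[str]
    cell_ids: list[str]
    coords: np.ndarray
    cell_type: np.ndarray | None = None
    platform: str = "bead"
    normalized: bool = False
    raw: np.ndarray | sparse.spmatrix | None = None

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.platform not in PLATFORMS:
            raise DataError(f"platform must be one of {PLATFORMS}, got {self.platform!r}")
        ng, nc = self.expr.shape
        if len(self.gene_ids) != ng:
            raise DataError(f"{len(self.gene_ids)} gene ids for {ng} expression rows")
        if len(self.cell_ids) != nc:
            raise DataError(f"{len(self.cell_ids)} cell ids for {nc} expression columns")
        if self.coords.shape != (nc, 2):
            raise DataError(f"coords shape {self.coords.shape} != ({nc}, 2)")
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise DataError(f"duplicate {name} ids")
        if self.cell_type is not None:
            self.cell_type = np.asarray(self.cell_type, dtype=object)
            if self.cell_type.shape != (nc,):
                raise DataError("cell_type must cover every cell")
        mn = self.expr.min() if not sparse.issparse(self.expr) else self.expr.tocoo().data.min(initial=0.0)
        if mn < 0:
            raise DataError("negative expression values")

    @property
    def n_genes(self) -> int:
        return self.expr.shape[0]

    @property
    def n_cells(self) -> int:
        return self.expr.shape[1]

    def expr_dense(self) -> np.ndarray:
        """Expression as a dense float array (genes x cells)."""
        if sparse.issparse(self.expr):
            return np.asarray(self.expr.todense(), dtype=float)
        return np.asarray(self.expr, dtype=float)

    def gene_index(self, genes: str | list[str]) -> np.ndarray:
        """Row indices for one gene or a list of genes (KeyError if absent)."""
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        if isinstance(genes, str):
            genes = [genes]
        try:
            return np.array([lookup[g] for g in genes], dtype=int)
        except KeyError as e:  # pragma: no cover - message only
            raise KeyError(f"gene {e.args[0]!r} not in dataset") from None


def normalize(ds: SpatialDataset) -> SpatialDataset:
    """Library-size scale each cell to the median depth, then log1p.

    Raw counts are preserved on the returned dataset's ``raw`` attribute.
    A no-op (returns ``ds``) when the dataset is already normalized.
    """
    if ds.normalized:
        return ds
    X = ds.expr_dense()
    depth = X.sum(axis=0)
    depth[depth == 0] = 1.0
    target = float(np.median(X.sum(axis=0))) or 1.0
    Xn = np.log1p(X / depth[None, :] * target)
    return replace(ds, expr=Xn, normalized=True, raw=ds.expr)


def _read_ids(path: Path) -> list[str]:
    return [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]


def read_spatial_dataset(
    expr_path: str | Path,
    coords_path: str | Path,
    labels_path: str | Path | None = None,
    platform: str = "bead",
    genes_path: str | Path | None = None,
    cells_path: str | Path | None = None,
) -> SpatialDataset:
    """Read expression (MTX triplet + ID sidecars, or dense CSV) and coordinates.

    Cells are reordered to the intersection of expression and coordinate IDs,
    in coordinate-file order; dropped IDs are logged.  The coordinate CSV must
    have columns ``cell_id,x,y``; the optional labels CSV ``cell_id,type``.
    """
    expr_path = Path(expr_path)
    if expr_path.suffix == ".mtx":
        genes_path = genes_path or expr_path.with_suffix(".genes.txt")
        cells_path = cells_path or expr_path.with_suffix(".cells.txt")
        mat = sparse.csc_matrix(spio.mmread(str(expr_path)))
        gene_ids = _read_ids(Path(genes_path))
        cell_ids = _read_ids(Path(cells_path))
        if mat.shape != (len(gene_ids), len(cell_ids)):
            raise DataError(
                f"MTX shape {mat.shape} does not match sidecar IDs "
                f"({len(gene_ids)} genes, {len(cell_ids)} cells)"
            )
    else:
        df = pd.read_csv(expr_path, index_col=0)
        gene_ids = [str(g).strip() for g in df.index]
        cell_ids = [str(c).strip() for c in df.columns]
        mat = df.to_numpy(dtype=float)

    coords_df = pd.read_csv(coords_path)
    for col in ("cell_id", "x", "y"):
        if col not in coords_df.columns:
            raise DataError(f"coords file lacks column {col!r}")
    coords_df["cell_id"] = coords_df["cell_id"].astype(str).str.strip()
    if coords_df["cell_id"].duplicated().any():
        raise DataError("duplicate cell ids in coordinates file")
    if len(set(cell_ids)) != len(cell_ids):
        raise DataError("duplicate cell ids in expression file")

    expr_pos = {c: i for i, c in enumerate(cell_ids)}
    keep = coords_df["cell_id"].isin(expr_pos).to_numpy()
    n_drop_coords = int((~keep).sum())
    n_drop_expr = len(cell_ids) - int(keep.sum())
    if n_drop_coords or n_drop_expr:
        logger.warning(
            "ID intersection: dropped %d coordinate-only and %d expression-only cells",
            n_drop_coords, n_drop_expr,
        )
    coords_df = coords_df.loc[keep]
    if coords_df.empty:
        raise DataError("no cells shared between expression and coordinates")
    order = [expr_pos[c] for c in coords_df["cell_id"]]
    mat = mat[:, order]
    final_cells = coords_df["cell_id"].tolist()
    coords = coords_df[["x", "y"]].to_numpy(dtype=float)

    cell_type = None
    if labels_path is not None:
        lab = pd.read_csv(labels_path)
        for col in ("cell_id", "type"):
            if col not in lab.columns:
                raise DataError(f"labels file lacks column {col!r}")
        lab["cell_id"] = lab["cell_id"].astype(str).str.strip()
        lab = lab.set_index("cell_id")["type"]
        missing = [c for c in final_cells if c not in lab.index]
        if missing:
            raise DataError(f"labels missing for {len(missing)} cells (e.g. {missing[0]!r})")
        cell_type = lab.loc[final_cells].astype(str).to_numpy(dtype=object)

    return SpatialDataset(
        expr=mat, gene_ids=gene_ids, cell_ids=final_cells, coords=coords,
        cell_type=cell_type, platform=platform,
    )


def write_spatial_dataset(ds: SpatialDataset, outdir: str | Path, stem: str = "expr") -> dict[str, Path]:
    """Write a dataset back to MTX + sidecars + coords (+ labels) CSV."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}
    mtx = outdir / f"{stem}.mtx"
    spio.mmwrite(str(mtx), sparse.coo_matrix(ds.expr))
    paths["expr"] = mtx
    (outdir / f"{stem}.genes.txt").write_text("\n".join(ds.gene_ids) + "\n")
    (outdir / f"{stem}.cells.txt").write_text("\n".join(ds.cell_ids) + "\n")
    paths["genes"] = outdir / f"{stem}.genes.txt"
    paths["cells"] = outdir / f"{stem}.cells.txt"
    coords = pd.DataFrame({"cell_id": ds.cell_ids, "x": ds.coords[:, 0], "y": ds.coords[:, 1]})
    coords.to_csv(outdir / "coords.csv", index=False)
    paths["coords"] = outdir / "coords.csv"
    if ds.cell_type is not None:
        lab = pd.DataFrame({"cell_id": ds.cell_ids, "type": ds.cell_type})
        lab.to_csv(outdir / "labels.csv", index=False)
        paths["labels"] = outdir / "labels.csv"
    return paths


@dataclass
class LigandReceptorDB:
    """Ligand-receptor interaction records with multi-subunit receptor units."""

    records: pd.DataFrame  # columns: ligand, receptor, pathway, subunits (tuple)

    @property
    def ligands(self) -> list[str]:
        """Ligand gene list, de-duplicated preserving first occurrence."""
        return list(dict.fromkeys(self.records["ligand"]))

    @property
    def n_ligands(self) -> int:
        return len(self.ligands)

    @property
    def receptor_subunits(self) -> set[str]:
        return {s for subs in self.records["subunits"] for s in subs}

    def units_for(self, ligand: str) -> list[tuple[str, tuple[str, ...]]]:
        """(receptor name, subunit tuple) pairs recorded for a ligand."""
        sub = self.records[self.records["ligand"] == ligand]
        return list(dict.fromkeys(zip(sub["receptor"], sub["subunits"])))


def read_lr_database(path: str | Path) -> LigandReceptorDB:
    """Read a CSV with columns ``ligand,receptor,pathway``; subunits split on ``_``."""
    df = pd.read_csv(path)
    for col in ("ligand", "receptor", "pathway"):
        if col not in df.columns:
            raise DataError(f"ligand-receptor file lacks column {col!r}")
    df = df[["ligand", "receptor", "pathway"]].astype(str).apply(lambda s: s.str.strip())
    if (df[["ligand", "receptor"]] == "").any().any():
        raise DataError("empty gene symbol in ligand-receptor file")
    df = df.copy()
    df["subunits"] = df["receptor"].map(lambda r: tuple(p for p in r.split("_") if p))
    if (df["subunits"].map(len) == 0).any():
        raise DataError("receptor unit with no subunits")
    return LigandReceptorDB(records=df.reset_index(drop=True))


@dataclass
class GeneSetCollection:
    """Named gene sets with a source tag (GO/KEGG/other)."""

    sets: dict[str, frozenset[str]] = field(default_factory=dict)
    source: str = "other"

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> frozenset[str]:
        return self.sets[name]

    def items(self):
        return self.sets.items()

    def subset(self, names) -> "GeneSetCollection":
        return GeneSetCollection({n: self.sets[n] for n in names if n in self.sets}, self.source)


def read_gmt(path: str | Path, source: str = "other") -> GeneSetCollection:
    """Read a GMT file (name, description, genes; tab-separated, one set per line)."""
    sets: dict[str, frozenset[str]] = {}
    text = Path(path).read_text()
    for i, line in enumerate(text.splitlines()):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 3:
            logger.warning("GMT line %d has <3 fields; skipped", i + 1)
            continue
        name = fields[0]
        genes = frozenset(g for g in fields[2:] if g)
        if not genes:
            logger.warning("GMT set %r is empty; skipped", name)
            continue
        if name in sets:
            raise DataError(f"duplicate gene-set name {name!r}")
        sets[name] = genes
    if not sets:
        logger.warning("GMT file %s contained no usable sets", path)
    return GeneSetCollection(sets=sets, source=source)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    lines = [
        "\t".join([name, collection.source] + sorted(genes))
        for name, genes in collection.items()
    ]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""))
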