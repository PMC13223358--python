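"""Input handling: gene coding, noise distance scores, spot conversion.

An imaging-based spatial transcriptomics (ST) experiment yields a table of
individual mRNA molecules, each with 2-D coordinates in micrometers and a
gene label.  The segmentation method additionally requires an scRNA-seq
reference (cells x genes counts with a per-cell type annotation).  Genes
detected in both modalities — the *intersection genes* — are coded with
positive integers 1..k in lexicographic order; every other ST gene is coded
k+1 and carries no expression information downstream.

The noise distance score (NDS) summarises local molecule density: for each
molecule the mean Euclidean distance to its d nearest neighbours is divided
by the q-quantile of those means over the dataset and clipped into [0, 1].
Isolated molecules (likely background) score near 0, molecules inside dense
cell bodies score near 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

try:  # optional container for references on disk
    import anndata as ad
except ImportError:  # pragma: no cover
    ad = None

logger = logging.getLogger(__name__)

__all__ = [
    "TranscriptTable",
    "ReferencePanel",
    "encode_genes",
    "compute_noise_distance_scores",
    "spots_to_molecules",
    "read_transcripts",
    "read_reference",
    "PLATFORM_COLUMNS",
]

#: Column-name dialects of common commercial exports (x, y, gene).
PLATFORM_COLUMNS = {
    "generic": ("x", "y", "gene"),
    "xenium": ("x_location", "y_location", "feature_name"),
    "cosmx": ("x_global_px", "y_global_px", "target"),
    "merfish": ("global_x", "global_y", "gene"),
    "merscope": ("global_x", "global_y", "gene"),
}


@dataclass
class TranscriptTable:
    """Per-molecule records: coordinates (um), raw gene, integer code, NDS."""

    x: np.ndarray
    y: np.ndarray
    raw_gene: np.ndarray
    gene_code: np.ndarray | None = None  # 1..k+1 once encoded
    nds: np.ndarray | None = None

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=np.float64)
        self.raw_gene = np.asarray(self.raw_gene, dtype=object)
        if not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("transcript coordinates must be finite")

    def __len__(self) -> int:
        return self.x.shape[0]

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    def subset(self, mask: np.ndarray) -> "TranscriptTable":
        return TranscriptTable(
            self.x[mask], self.y[mask], self.raw_gene[mask],
            None if self.gene_code is None else self.gene_code[mask],
            None if self.nds is None else self.nds[mask],
        )

    def to_frame(self) -> pd.DataFrame:
        d = {"x": self.x, "y": self.y, "gene": self.raw_gene}
        if self.gene_code is not None:
            d["gene_code"] = self.gene_code
        if self.nds is not None:
            d["nds"] = self.nds
        return pd.DataFrame(d)


@dataclass
class ReferencePanel:
    """scRNA-seq reference restricted to the intersection gene panel.

    ``S`` is cells x k over the intersection genes (the working matrix);
    ``U`` is cells x m over the full measured transcriptome and is used only
    for whole-transcriptome imputation.
    """

    S: np.ndarray
    U: np.ndarray
    cell_type: np.ndarray
    gene_ids: list[str]
    all_genes: list[str]
    types: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.S = np.asarray(self.S, dtype=np.float64)
        self.U = np.asarray(self.U, dtype=np.float64)
        self.cell_type = np.asarray(self.cell_type, dtype=object)
        if not self.types:
            self.types = sorted(set(self.cell_type.tolist()))
        if self.S.shape[0] != self.U.shape[0]:
            raise ValueError("S and U must describe the same cells")
        if len(self.gene_ids) < 1:
            raise ValueError("intersection gene panel is empty")

    @property
    def n_cells(self) -> int:
        return self.S.shape[0]

    @property
    def k(self) -> int:
        return len(self.gene_ids)

    def cells_of_type(self, t: str) -> np.ndarray:
        return np.flatnonzero(self.cell_type == t)


def encode_genes(
    transcripts: pd.DataFrame | TranscriptTable,
    reference,
    cell_type_key: str = "cell_type",
    top_genes: int | None = None,
) -> tuple[TranscriptTable, ReferencePanel]:
    """Code intersection genes 1..k (sorted) and build the reference panel.

    Parameters
    ----------
    transcripts
        Molecule records with ``x``, ``y``, ``gene`` columns (or a
        :class:`TranscriptTable`).
    reference
        An ``AnnData`` (cells x genes, ``obs[cell_type_key]``) or a tuple
        ``(counts, gene_names, cell_types)``.
    top_genes
        If given, only the ``top_genes`` intersection genes with the highest
        total molecule counts in the ST data keep distinct codes; the rest
        are coded k+1 together with non-shared genes.  Used for the
        sequencing-based (spot) adaptation.
    """
    if isinstance(transcripts, TranscriptTable):
        table = transcripts
    else:
        table = TranscriptTable(
            transcripts["x"].to_numpy(),
            transcripts["y"].to_numpy(),
            transcripts["gene"].to_numpy(),
        )

    counts, ref_genes, cell_types = _unpack_reference(reference, cell_type_key)

    st_genes = set(map(str, table.raw_gene.tolist()))
    shared = sorted(st_genes.intersection(ref_genes))
    if not shared:
        raise ValueError(
            f"no genes shared between ST data ({len(st_genes)} genes) and "
            f"reference ({len(ref_genes)} genes)"
        )

    if top_genes is not None and top_genes < len(shared):
        st_totals = pd.Series(table.raw_gene).value_counts()
        ranked = sorted(shared, key=lambda g: (-st_totals.get(g, 0), g))
        shared = sorted(ranked[:top_genes])

    code_of = {g: i + 1 for i, g in enumerate(shared)}
    k = len(shared)
    gene_code = np.array(
        [code_of.get(str(g), k + 1) for g in table.raw_gene], dtype=np.int64
    )
    table = TranscriptTable(table.x, table.y, table.raw_gene, gene_code, table.nds)

    col_of = {g: j for j, g in enumerate(ref_genes)}
    sel = [col_of[g] for g in shared]
    panel = ReferencePanel(
        S=counts[:, sel],
        U=counts,
        cell_type=cell_types,
        gene_ids=shared,
        all_genes=list(ref_genes),
    )
    return table, panel


def _unpack_reference(reference, cell_type_key):
    if ad is not None and isinstance(reference, ad.AnnData):
        X = reference.X
        counts = np.asarray(X.todense() if hasattr(X, "todense") else X, dtype=np.float64)
        genes = [str(g) for g in reference.var_names]
        cell_types = reference.obs[cell_type_key].to_numpy().astype(object)
    else:
        counts, genes, cell_types = reference
        counts = np.asarray(
            counts.todense() if hasattr(counts, "todense") else counts,
            dtype=np.float64,
        )
        genes = [str(g) for g in genes]
        cell_types = np.asarray(cell_types, dtype=object)
    return counts, genes, cell_types


def quantile(values: np.ndarray, q: float) -> float:
    """The quantile convention used throughout (NDS, CDS, node cutoffs):
    linear interpolation between order statistics (NumPy's default)."""
    return float(np.quantile(np.asarray(values, dtype=np.float64), q))


def compute_noise_distance_scores(
    table: TranscriptTable, d: int = 100, q: float = 0.999
) -> np.ndarray:
    """Per-molecule noise distance scores in [0, 1].

    NDS_i = max(0, 1 - d_i / Q(d, q)) where d_i is the mean distance from
    molecule i to its d nearest neighbours (self excluded) and Q is the
    q-quantile of all d_i.  If every molecule is coincident (Q = 0) the
    score is defined as 1 for all molecules.
    """
    n = len(table)
    if n <= d:
        raise ValueError(f"need more than d={d} molecules, got n={n}")
    if not 0.0 < q < 1.0:
        raise ValueError("q must lie in (0, 1)")
    pts = table.coords
    tree = cKDTree(pts)
    # k+1 neighbours: the first is the point itself (distance 0)
    dists, _ = tree.query(pts, k=d + 1)
    mean_d = dists[:, 1:].mean(axis=1)
    Q = quantile(mean_d, q)
    if Q == 0.0:
        nds = np.ones(n)
    else:
        nds = np.maximum(0.0, 1.0 - mean_d / Q)
    table.nds = nds
    return nds


def spots_to_molecules(
    spot_counts: np.ndarray,
    spot_coords: np.ndarray,
    gene_names,
) -> TranscriptTable:
    """Expand a spots x genes count matrix into per-UMI molecule records.

    Every count unit becomes one molecule at its spot's coordinates, which
    makes sequencing-based (spot) data consumable by the same pipeline as
    imaging-based data.  Duplicate coordinates are expected and legal.
    The top-gene cap of the spot adaptation is applied later via
    ``encode_genes(top_genes=...)``, and the NDS/CDS quantile is typically
    raised to 0.9999 for such data.
    """
    counts = np.asarray(
        spot_counts.todense() if hasattr(spot_counts, "todense") else spot_counts
    )
    coords = np.asarray(spot_coords, dtype=np.float64)
    if counts.shape[0] != coords.shape[0]:
        raise ValueError("spot_counts and spot_coords disagree on spot number")
    if np.any(counts < 0) or not np.allclose(counts, np.round(counts)):
        raise ValueError("spot counts must be nonnegative integers")
    counts = counts.astype(np.int64)
    gene_names = np.asarray(list(gene_names), dtype=object)

    spot_idx, gene_idx = np.nonzero(counts)
    reps = counts[spot_idx, gene_idx]
    spot_rep = np.repeat(spot_idx, reps)
    gene_rep = np.repeat(gene_idx, reps)
    return TranscriptTable(
        coords[spot_rep, 0], coords[spot_rep, 1], gene_names[gene_rep]
    )


# ---------------------------------------------------------------------------
# file readers
# ---------------------------------------------------------------------------

def read_transcripts(
    path,
    platform: str = "generic",
    x: str | None = None,
    y: str | None = None,
    gene: str | None = None,
    sep: str | None = None,
) -> pd.DataFrame:
    """Read a molecule table from delimited text or Parquet.

    ``platform`` selects a column-name preset (see :data:`PLATFORM_COLUMNS`);
    explicit ``x``/``y``/``gene`` override it.  Any z coordinate present in
    the file is ignored: the method operates strictly in 2-D.
    """
    cx, cy, cg = PLATFORM_COLUMNS.get(platform.lower(), PLATFORM_COLUMNS["generic"])
    cx, cy, cg = x or cx, y or cy, gene or cg
    path = str(path)
    if path.endswith(".parquet"):
        df = pd.read_parquet(path)
    else:
        if sep is None:
            sep = "\t" if path.endswith((".tsv", ".tsv.gz")) else ","
        df = pd.read_csv(path, sep=sep)
    for col in (cx, cy, cg):
        if col not in df.columns:
            raise ValueError(f"column {col!r} not found in {path}")
    if any(c in df.columns for c in ("z", "z_location", "global_z")):
        logger.warning("ignoring z coordinate column: the pipeline is 2-D")
    out = df[[cx, cy, cg]].copy()
    out.columns = ["x", "y", "gene"]
    return out


def read_reference(path, cell_type_key: str = "cell_type"):
    """Read an scRNA-seq reference from .h5ad, or from an MTX prefix.

    For MTX input, ``path`` is a prefix such that ``<path>.mtx``,
    ``<path>_genes.tsv`` and ``<path>_cells.tsv`` exist; the cells TSV must
    contain a ``cell_type`` column (name configurable).
    Returns ``(counts, gene_names, cell_types)``.
    """
    path = str(path)
    if path.endswith(".h5ad"):
        if ad is None:  # pragma: no cover
            raise ImportError("anndata is required to read .h5ad files")
        adata = ad.read_h5ad(path)
        return _unpack_reference(adata, cell_type_key)
    from scipy.io import mmread

    counts = np.asarray(mmread(path + ".mtx").todense(), dtype=np.float64)
    genes = pd.read_csv(path + "_genes.tsv", sep="\t", header=None)[0].astype(str).tolist()
    cells = pd.read_csv(path + "_cells.tsv", sep="\t")
    if cell_type_key not in cells.columns:
        raise ValueError(f"cells TSV lacks a {cell_type_key!r} column")
    return counts, genes, cells[cell_type_key].to_numpy().astype(object)
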