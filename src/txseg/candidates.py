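"""Prior candidate cell centres from marker-gene spatial density.

The cascade: (1) score marker genes per cell type from the normalised
reference, (2) summarise each marker's spatial distribution on a grid and
cluster markers into spatially coherent categories, (3) per category,
select high-density grid nodes, group the nearby molecules with DBSCAN,
split each group into candidate cells with K-means (the K formula scales
with group size and the category's expression threshold), and (4) merge
all categories' centres with MeanShift.

Candidate centres only seed the assignment policy; they may equally come
from nuclei or any external source.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree
from sklearn.cluster import DBSCAN, KMeans, MeanShift, AgglomerativeClustering

from .preprocess import ReferencePanel, TranscriptTable, quantile

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerScoreMatrix",
    "CandidateSet",
    "score_markers",
    "grid_node_features",
    "cluster_marker_categories",
    "select_valid_nodes",
    "cluster_molecules_to_candidates",
    "merge_candidates",
    "estimate_candidates",
]

#: fixed per-cell total used when normalising the reference before averaging
NORM_TOTAL = 1e4


@dataclass
class MarkerScoreMatrix:
    """Marker scores S = ln(A + 1) * P per gene and type.

    A is the mean normalised expression, P the fraction of a gene's total
    mean expression falling in each type (rows of P sum to 1 where the
    gene is expressed at all).
    """

    scores: pd.DataFrame  # genes x types
    A: pd.DataFrame
    P: pd.DataFrame
    markers: list[str]  # union of per-type top-p markers, deduplicated


@dataclass
class CandidateSet:
    centers: np.ndarray  # c x 2 (um)
    provenance: str = "estimated"  # estimated | external | nuclear

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=np.float64))
        if self.centers.size == 0:
            raise ValueError("candidate set is empty")
        if not np.isfinite(self.centers).all():
            raise ValueError("candidate centers must be finite")

    def __len__(self) -> int:
        return self.centers.shape[0]


def score_markers(reference: ReferencePanel, p: int = 3) -> MarkerScoreMatrix:
    """Select the top-``p`` marker genes per cell type.

    The reference is count-normalised per cell to a fixed total before
    averaging; the natural logarithm is used throughout.
    """
    totals = reference.S.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    norm = reference.S / totals * NORM_TOTAL
    types = reference.types
    A = np.column_stack([
        norm[reference.cells_of_type(t)].mean(axis=0) if
        len(reference.cells_of_type(t)) else np.zeros(reference.k)
        for t in types
    ])
    row_tot = A.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        P = np.where(row_tot > 0, A / np.where(row_tot > 0, row_tot, 1.0), 0.0)
    S = np.log(A + 1.0) * P

    genes = reference.gene_ids
    markers: list[str] = []
    for j, t in enumerate(types):
        col = S[:, j]
        nonzero = np.flatnonzero(col > 0)
        if len(nonzero) < p:
            logger.warning(
                "type %s has only %d genes with nonzero marker score (wanted %d)",
                t, len(nonzero), p,
            )
        # sort by descending score, ties by gene name for determinism
        order = sorted(range(len(genes)), key=lambda i: (-col[i], genes[i]))
        chosen = [genes[i] for i in order[:p] if col[i] > 0]
        for g in chosen:
            if g not in markers:
                markers.append(g)
    frame = lambda M: pd.DataFrame(M, index=genes, columns=types)
    return MarkerScoreMatrix(frame(S), frame(A), frame(P), markers)


def _grid_nodes(coords: np.ndarray, spacing: float) -> np.ndarray:
    lo = coords.min(axis=0)
    hi = coords.max(axis=0)
    xs = np.arange(lo[0], hi[0] + spacing, spacing)
    ys = np.arange(lo[1], hi[1] + spacing, spacing)
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def grid_node_features(
    table: TranscriptTable, markers: list[str], r: float
) -> tuple[np.ndarray, np.ndarray]:
    """Marker counts near grid nodes; returns (F, nodes).

    The grid spans the molecule bounding box at spacing 2r; F[g, node]
    counts marker-gene-g molecules within 2r/pi of the node, then each
    column (node) is standardised to mean 0, sd 1 (all-zero sd -> zeros).
    """
    if r <= 0:
        raise ValueError("prior cell radius r must be positive")
    nodes = _grid_nodes(table.coords, 2.0 * r)
    radius = 2.0 * r / np.pi
    F = np.zeros((len(markers), nodes.shape[0]))
    any_marker = False
    for gi, g in enumerate(markers):
        mask = table.raw_gene == g
        if not mask.any():
            continue
        any_marker = True
        tree = cKDTree(table.coords[mask])
        F[gi] = tree.query_ball_point(nodes, radius, return_length=True)
    if not any_marker:
        raise ValueError("no marker-gene molecules found in the transcript table")
    mu = F.mean(axis=0, keepdims=True)
    sd = F.std(axis=0, keepdims=True)
    sd[sd == 0] = np.inf  # zero-variance columns -> zeros
    F = (F - mu) / sd
    return F, nodes


def cluster_marker_categories(
    F: np.ndarray, A: pd.DataFrame, markers: list[str], c: int = 10
) -> tuple[np.ndarray, np.ndarray]:
    """Group markers into ``c`` spatially coherent categories.

    Similarity is the pairwise Pearson correlation of the rows of F;
    agglomerative (average-linkage) clustering runs on 1 - correlation.
    Returns (category label per marker, threshold vector t per category)
    where t_c sums, over the category's genes, each gene's maximum mean
    expression across types.
    """
    m = len(markers)
    if m < c:
        logger.warning("only %d markers for %d categories; reducing c", m, c)
        c = m
    if m == c:
        labels = np.arange(m)
    else:
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(F)
        corr = np.nan_to_num(corr, nan=0.0)
        np.fill_diagonal(corr, 1.0)
        dist = 1.0 - corr
        model = AgglomerativeClustering(
            n_clusters=c, metric="precomputed", linkage="average"
        )
        labels = model.fit_predict(dist)
    max_per_gene = A.loc[markers].max(axis=1).to_numpy()
    t = np.array([max_per_gene[labels == cat].sum() for cat in range(c)])
    return labels, t


def select_valid_nodes(h: np.ndarray, q: float = 0.9) -> np.ndarray:
    """Boolean mask of valid (high-density) nodes for one category.

    cutoff1 = Q(h, q) * 0.01; cutoff2 = mean of h over nodes with
    h > cutoff1; valid nodes have h > cutoff2 (strict).
    """
    h = np.asarray(h, dtype=np.float64)
    if h.size == 0:
        return np.zeros(0, dtype=bool)
    cutoff1 = quantile(h, q) * 0.01
    above = h > cutoff1
    if not above.any():
        logger.warning("no node exceeds the primary density cutoff")
        return np.zeros_like(h, dtype=bool)
    cutoff2 = h[above].mean()
    valid = h > cutoff2
    if not valid.any():
        logger.warning("no valid nodes for this category (degenerate density)")
    return valid


def cluster_molecules_to_candidates(
    points: np.ndarray,
    r: float,
    max_t: float,
    t_c: float,
    seed: int = 0,
    min_samples: int = 3,
) -> np.ndarray:
    """DBSCAN -> K-means split of one category's molecules into centres.

    DBSCAN (eps = 2r) groups the molecules; each group of size h is split
    into k = max(1, int(0.25 * h * ln(max_t / t_c + 1))) K-means clusters
    and the cluster mean coordinates become candidate centres.
    ``min_samples`` defaults to 3 rather than sklearn's 5: a single cell
    contributes only a handful of molecules of any one marker category,
    and the valid-node prefilter already suppresses stray background.
    """
    points = np.atleast_2d(np.asarray(points, dtype=np.float64))
    if points.shape[0] == 0:
        return np.zeros((0, 2))
    if points.shape[0] < 2:
        return points.copy()
    labels = DBSCAN(eps=2.0 * r, min_samples=min_samples).fit_predict(points)
    centers = []
    log_term = float(np.log(max_t / t_c + 1.0)) if t_c > 0 else np.log(2.0)
    for lab in np.unique(labels):
        if lab < 0:
            continue  # DBSCAN noise
        grp = points[labels == lab]
        h = grp.shape[0]
        k = max(1, int(0.25 * h * log_term))
        k = min(k, h)
        if k == 1:
            centers.append(grp.mean(axis=0))
            continue
        km = KMeans(n_clusters=k, n_init=10, random_state=seed).fit(grp)
        for kl in range(k):
            sub = grp[km.labels_ == kl]
            if len(sub):
                centers.append(sub.mean(axis=0))
    if not centers:
        return np.zeros((0, 2))
    return np.vstack(centers)


def merge_candidates(centers: np.ndarray, r: float) -> CandidateSet:
    """MeanShift (bandwidth r/5) merge of pooled per-category centres."""
    centers = np.atleast_2d(np.asarray(centers, dtype=np.float64))
    if centers.shape[0] == 0:
        raise ValueError("no candidate centers to merge")
    if centers.shape[0] == 1:
        return CandidateSet(centers, provenance="estimated")
    ms = MeanShift(bandwidth=r / 5.0).fit(centers)
    return CandidateSet(ms.cluster_centers_, provenance="estimated")


def estimate_candidates(
    table: TranscriptTable,
    reference: ReferencePanel,
    r: float = 6.5,
    p: int = 3,
    c: int = 10,
    q: float = 0.9,
    seed: int = 0,
    min_samples: int = 3,
) -> CandidateSet:
    """Full cascade from transcripts + reference to candidate centres.

    ``r`` is the prior cell radius in micrometers (6.5 suits Xenium-scale
    resolution), ``p`` the markers per type, ``c`` the number of marker
    categories and ``q`` the node-density quantile.
    """
    msm = score_markers(reference, p=p)
    F, nodes = grid_node_features(table, msm.markers, r)
    labels, t = cluster_marker_categories(F, msm.A, msm.markers, c=c)
    max_t = float(t.max()) if len(t) else 0.0

    node_tree = None
    all_centers = []
    assoc_radius = 2.0 * r  # one grid spacing: molecule-to-node adjacency
    for cat in range(len(t)):
        cat_genes = [g for g, lab in zip(msm.markers, labels) if lab == cat]
        mask = np.isin(table.raw_gene, cat_genes)
        if not mask.any():
            continue
        pts = table.coords[mask]
        tree = cKDTree(pts)
        h = tree.query_ball_point(nodes, assoc_radius, return_length=True)
        valid = select_valid_nodes(h, q=q)
        if not valid.any():
            continue
        node_tree = cKDTree(nodes[valid])
        near = node_tree.query_ball_point(pts, assoc_radius, return_length=True) > 0
        if not near.any():
            continue
        cand = cluster_molecules_to_candidates(
            pts[near], r, max_t, float(t[cat]), seed=seed,
            min_samples=min_samples,
        )
        if len(cand):
            all_centers.append(cand)
    if not all_centers:
        raise ValueError("candidate estimation produced no centers")
    return merge_candidates(np.vstack(all_centers), r)
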