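"""Polygonal boundaries, assignment refinement, whole-transcriptome
imputation, and the nuclear-prior variant.

Cell bodies are traced as alpha shapes of each cell's assigned molecule
coordinates (the alpha -> 0 limit is the convex hull).  Molecules falling
outside their cell's polygon are conservatively reclassified as noise.
Whole-transcriptome profiles are imputed per segmented cell as a weighted
average of its most similar reference cells, where each reference cell's
weight is its cosine similarity times an occurrence score ln(n / O) that
down-weights reference cells matched by many segmented cells.
"""

from __future__ import annotations

import json
import logging

import numpy as np
import shapely
from scipy.spatial import Delaunay
from shapely.geometry import Polygon, mapping
from shapely.ops import unary_union

from .preprocess import ReferencePanel, TranscriptTable
from .train import SegmentationResult, aggregate_expression

logger = logging.getLogger(__name__)

__all__ = [
    "alpha_shape",
    "polygonal_boundaries",
    "refine_assignments",
    "occurrence_scores",
    "imputation_weights",
    "impute_transcriptome",
    "nuclear_pair_offsets",
    "apply_nuclear_priors",
    "polygons_to_geojson",
    "write_geojson",
]


def _circumradii(points: np.ndarray, simplices: np.ndarray) -> np.ndarray:
    a = points[simplices[:, 0]]
    b = points[simplices[:, 1]]
    c = points[simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    area = 0.5 * np.abs(
        (b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1])
        - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1])
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (4.0 * area)
    r[~np.isfinite(r)] = np.inf  # degenerate (collinear) triangles
    return r


def _union_of(points, simplices, keep):
    polys = [Polygon(points[s]) for s in simplices[keep]]
    return unary_union(polys)


def alpha_shape(points: np.ndarray, alpha: float | None = None):
    """Alpha shape of a 2-D point cloud as a shapely Polygon, or None.

    Delaunay triangles with circumradius >= 1/alpha are discarded and the
    rest unioned; ``alpha=0`` keeps everything (the convex hull).  With
    ``alpha=None`` the largest alpha is chosen (by bisection over the
    observed circumradii) for which the shape remains a single polygon
    touching every point; degenerate inputs (< 3 points, collinear) return
    None.
    """
    points = np.unique(np.asarray(points, dtype=np.float64), axis=0)
    if points.shape[0] < 3:
        return None
    try:
        tri = Delaunay(points)
    except Exception:
        return None  # collinear or otherwise degenerate
    simplices = tri.simplices
    radii = _circumradii(points, simplices)
    if not np.isfinite(radii).any():
        return None

    if alpha is not None and alpha > 0:
        keep = radii < 1.0 / alpha
        if not keep.any():
            return None
        geom = _union_of(points, simplices, keep)
    elif alpha == 0 or alpha is None:
        hull = _union_of(points, simplices, np.ones(len(simplices), bool))
        if alpha == 0:
            geom = hull
        else:
            # automatic: tightest threshold keeping one polygon over all points
            levels = np.unique(radii[np.isfinite(radii)])
            lo, hi = 0, len(levels) - 1
            best = None
            while lo <= hi:
                mid = (lo + hi) // 2
                keep = radii <= levels[mid]
                cand = _union_of(points, simplices, keep)
                if (
                    isinstance(cand, Polygon)
                    and cand.area > 0
                    and len(np.unique(simplices[keep])) == points.shape[0]
                ):
                    best = cand
                    hi = mid - 1
                else:
                    lo = mid + 1
            geom = best if best is not None else hull
    else:
        raise ValueError("alpha must be None or >= 0")

    if isinstance(geom, Polygon) and geom.area > 0:
        return geom
    if geom.geom_type == "MultiPolygon":
        largest = max(geom.geoms, key=lambda g: g.area)
        return largest if largest.area > 0 else None
    return None


def polygonal_boundaries(
    table: TranscriptTable,
    result: SegmentationResult,
    alpha: float | None = None,
    min_molecules: int = 3,
) -> tuple[dict[int, Polygon], list[int]]:
    """Per-cell polygons from assigned molecule coordinates.

    Returns ``(polygons, degenerate)``: cells with fewer than three
    non-collinear molecules are flagged degenerate (no polygon) but remain
    in the count matrix.
    """
    polygons: dict[int, Polygon] = {}
    degenerate: list[int] = []
    coords = table.coords
    keep = ~result.noise
    for cell in np.unique(result.cell[keep]):
        pts = coords[keep & (result.cell == cell)]
        poly = alpha_shape(pts, alpha=alpha) if len(pts) >= min_molecules else None
        if poly is None:
            degenerate.append(int(cell))
        else:
            polygons[int(cell)] = poly
    return polygons, degenerate


def refine_assignments(
    table: TranscriptTable,
    result: SegmentationResult,
    polygons: dict[int, Polygon],
    k: int | None = None,
) -> SegmentationResult:
    """Reclassify molecules lying outside their cell's polygon as noise.

    Conservative: no reassignment to other cells.  Expression profiles are
    re-aggregated afterwards so count conservation holds.
    """
    noise = result.noise.copy()
    keep = ~result.noise
    for cell, poly in polygons.items():
        sel = np.flatnonzero(keep & (result.cell == cell))
        if len(sel) == 0:
            continue
        inside = shapely.intersects_xy(poly, table.x[sel], table.y[sel])
        noise[sel[~inside]] = True
    k = k if k is not None else result.E.shape[1]
    E = aggregate_expression(result.cell, noise, table.gene_code,
                             len(result.candidates), k)
    return SegmentationResult(cell=result.cell, noise=noise, E=E,
                              candidates=result.candidates)


def occurrence_scores(top_r: np.ndarray, n_reference: int) -> np.ndarray:
    """OS_j = ln(n / O_j) per reference cell.

    ``top_r`` holds each of the n segmented cells' most-similar reference
    cell indices; O_j counts the lists containing reference cell j.
    Reference cells chosen by every segmented cell score 0 (no weight),
    rarely-chosen cells score up to ln(n).  Unchosen cells keep score 0
    and are never queried.
    """
    n = top_r.shape[0]
    occ = np.zeros(n_reference)
    np.add.at(occ, top_r.ravel(), 1.0)
    out = np.zeros(n_reference)
    chosen = occ > 0
    out[chosen] = np.log(n / occ[chosen])
    return out


def imputation_weights(
    E: np.ndarray, reference: ReferencePanel, r: int = 40, k: int = 20
):
    """Top reference cells and their normalised weights per segmented cell.

    Returns ``(top_cells, weights, os)`` where ``top_cells`` is n x k,
    ``weights`` rows are sorted descending and sum to 1, and ``os`` are
    the per-reference-cell occurrence scores.
    """
    if r < k:
        raise ValueError("r must be >= k")
    E = np.asarray(E, dtype=np.float64)
    n = E.shape[0]
    log_e = np.log1p(E)
    log_s = np.log1p(reference.S)
    ne = np.linalg.norm(log_e, axis=1, keepdims=True)
    ns = np.linalg.norm(log_s, axis=1, keepdims=True)
    ne[ne == 0] = 1.0
    ns[ns == 0] = 1.0
    A = (log_e / ne) @ (log_s / ns).T  # n x s cosine matrix

    r_eff = min(r, A.shape[1])
    k_eff = min(k, r_eff)
    top_r = np.argsort(-A, axis=1, kind="stable")[:, :r_eff]
    os_score = occurrence_scores(top_r, A.shape[1])

    weights = A[np.arange(n)[:, None], top_r] * os_score[top_r]
    order = np.argsort(-weights, axis=1, kind="stable")[:, :k_eff]
    rows = np.arange(n)[:, None]
    top_cells = top_r[rows, order]
    top_w = np.maximum(weights[rows, order], 0.0)
    sums = top_w.sum(axis=1, keepdims=True)
    bad = sums[:, 0] <= 0
    if bad.any():
        logger.warning("%d cells had all-zero imputation weights; using "
                       "uniform weights over their top matches", int(bad.sum()))
        top_w[bad] = 1.0
        sums = top_w.sum(axis=1, keepdims=True)
    return top_cells, top_w / sums, os_score


def impute_transcriptome(
    E: np.ndarray,
    reference: ReferencePanel,
    r: int = 40,
    k: int = 20,
    cells: np.ndarray | None = None,
) -> np.ndarray:
    """Whole-transcriptome profiles for segmented cells.

    Similarity A = cosine of ln(1 + expression) over the intersection
    genes; each segmented cell's r most similar reference cells define
    occurrences O_j, occurrence scores OS_j = ln(n / O_j), and chosen
    weights similarity x OS.  The top k weights (descending, renormalised
    to sum 1) average the reference cells' full-transcriptome profiles,
    making every imputed profile a convex combination of reference cells.
    """
    E = np.asarray(E, dtype=np.float64)
    if cells is not None:
        E = E[cells]
    top_cells, top_w, _ = imputation_weights(E, reference, r=r, k=k)
    return np.einsum("nk,nkg->ng", top_w, reference.U[top_cells])


# ---------------------------------------------------------------------------
# nuclear-prior mode
# ---------------------------------------------------------------------------

def nuclear_pair_offsets(
    table: TranscriptTable,
    nuclei: list[Polygon],
    neighbor_idx: np.ndarray,
) -> np.ndarray:
    """Molecule-to-nucleus offsets replacing the centre offsets.

    The offset of a (molecule, candidate-nucleus) pair points from the
    nearest point of the nuclear boundary to the molecule, with magnitude
    equal to that distance; it is the zero vector for molecules inside the
    nucleus.  A molecule inside several overlapping candidate nuclei keeps
    the zero offset only for the nucleus with the nearest centroid.
    """
    n, m = neighbor_idx.shape
    coords = table.coords
    offsets = np.zeros((n, m, 2))
    centroids = np.array([[p.centroid.x, p.centroid.y] for p in nuclei])
    inside = np.zeros((n, m), dtype=bool)
    for j_slot in range(m):
        nuc_idx = neighbor_idx[:, j_slot]
        for nuc in np.unique(nuc_idx):
            sel = np.flatnonzero(nuc_idx == nuc)
            poly = nuclei[int(nuc)]
            inn = shapely.intersects_xy(poly, coords[sel, 0], coords[sel, 1])
            inside[sel, j_slot] = inn
            out = sel[~inn]
            if len(out):
                pts = shapely.points(coords[out])
                lines = shapely.shortest_line(poly.exterior, pts)
                nearest = shapely.get_coordinates(lines)[0::2]
                offsets[out, j_slot] = coords[out] - nearest
    multi = inside.sum(axis=1) > 1
    if multi.any():
        logger.info("%d molecules fall inside several nuclei; keeping the "
                    "nearest-centroid nucleus only", int(multi.sum()))
        for i in np.flatnonzero(multi):
            slots = np.flatnonzero(inside[i])
            cents = centroids[neighbor_idx[i, slots]]
            d = np.linalg.norm(cents - coords[i], axis=1)
            for s in slots[np.argsort(d, kind="stable")[1:]]:
                poly = nuclei[int(neighbor_idx[i, s])]
                pts = shapely.points(coords[i:i + 1])
                line = shapely.shortest_line(poly.exterior, pts)
                nearest = shapely.get_coordinates(line)[0]
                offsets[i, s] = coords[i] - nearest
    return offsets


def apply_nuclear_priors(
    polygons: dict[int, Polygon],
    nuclei: list[Polygon],
) -> dict[int, Polygon]:
    """Clip alpha-shape cell polygons against foreign nuclei and union each
    with its own nucleus (cell index == nucleus index)."""
    tree = shapely.STRtree(nuclei)
    out: dict[int, Polygon] = {}
    for cell, poly in polygons.items():
        own = nuclei[cell] if cell < len(nuclei) else None
        hits = tree.query(poly, predicate="intersects")
        clipped = poly
        for h in hits:
            if int(h) == cell:
                continue
            clipped = clipped.difference(nuclei[int(h)])
        if own is not None:
            clipped = unary_union([clipped, own])
        if clipped.geom_type == "MultiPolygon":
            if own is not None:
                # keep the piece holding the cell's own nucleus
                clipped = max(clipped.geoms,
                              key=lambda g: g.intersection(own).area)
            else:
                clipped = max(clipped.geoms, key=lambda g: g.area)
        if not clipped.is_empty and clipped.area > 0:
            out[cell] = clipped
    return out


# ---------------------------------------------------------------------------
# serialisation
# ---------------------------------------------------------------------------

def polygons_to_geojson(polygons: dict[int, Polygon]) -> dict:
    """GeoJSON FeatureCollection with a ``cell_id`` property per polygon."""
    features = [
        {
            "type": "Feature",
            "geometry": mapping(poly),
            "properties": {"cell_id": int(cell)},
        }
        for cell, poly in sorted(polygons.items())
    ]
    return {"type": "FeatureCollection", "features": features}


def write_geojson(path, polygons: dict[int, Polygon]) -> None:
    with open(path, "w") as fh:
        json.dump(polygons_to_geojson(polygons), fh)
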