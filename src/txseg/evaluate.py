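"""Benchmarking metrics: expression similarity, boundary agreement,
morphology, masked-gene imputation accuracy and label transfer.

Expression similarity follows the top-20 protocol: each segmented cell's
profile (scaled so its total equals the number of intersection genes) is
compared against every reference cell by cosine similarity and RMSE, and
SIM_C / SIM_R are the means of the 20 best values of each.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import gaussian_kde

from .preprocess import ReferencePanel, TranscriptTable, encode_genes

logger = logging.getLogger(__name__)

__all__ = [
    "SimilarityReport",
    "BoundaryReport",
    "expression_similarity_metrics",
    "boundary_agreement",
    "roundness",
    "morphology_metrics",
    "label_transfer",
    "imputation_benchmark",
]

TOP_MATCHES = 20


@dataclass
class SimilarityReport:
    sim_c: np.ndarray  # per-cell mean of top-20 cosine similarities
    sim_r: np.ndarray  # per-cell mean of 20 lowest RMSEs


@dataclass
class BoundaryReport:
    sensitivity: float  # mean IoU: truth cells vs nearest segmented cell
    specificity: float  # mean IoU: segmented cells vs nearest truth cell
    morphology_iou: dict[str, float] | None = None


def _normalise_total(M: np.ndarray, total: float) -> np.ndarray:
    sums = M.sum(axis=1, keepdims=True)
    sums[sums == 0] = 1.0
    return M / sums * total


def expression_similarity_metrics(
    segmented: np.ndarray, reference: np.ndarray, top: int = TOP_MATCHES
) -> SimilarityReport:
    """SIM_C and SIM_R per segmented cell against all reference cells.

    Both matrices must be restricted to the same gene panel; each cell's
    total is scaled to equal the number of genes before comparison.
    """
    A = _normalise_total(np.asarray(segmented, dtype=np.float64), segmented.shape[1])
    B = _normalise_total(np.asarray(reference, dtype=np.float64), segmented.shape[1])
    if B.shape[0] < top:
        logger.warning("reference has only %d cells (< %d); using all",
                       B.shape[0], top)
        top = B.shape[0]
    k = A.shape[1]
    na = np.linalg.norm(A, axis=1, keepdims=True)
    nb = np.linalg.norm(B, axis=1, keepdims=True)
    na[na == 0] = 1.0
    nb[nb == 0] = 1.0
    cos = (A / na) @ (B / nb).T
    # RMSE_ij^2 = (|A_i|^2 + |B_j|^2 - 2 A_i.B_j) / k
    sq = ((na**2) + (nb**2).T - 2.0 * (A @ B.T)) / k
    rmse = np.sqrt(np.maximum(sq, 0.0))
    cos_sorted = np.sort(cos, axis=1)[:, ::-1]
    rmse_sorted = np.sort(rmse, axis=1)
    return SimilarityReport(
        sim_c=cos_sorted[:, :top].mean(axis=1),
        sim_r=rmse_sorted[:, :top].mean(axis=1),
    )


def _centroids(polys) -> np.ndarray:
    return np.array([[p.centroid.x, p.centroid.y] for p in polys])


def _iou(a, b) -> float:
    u = a.union(b).area
    return a.intersection(b).area / u if u > 0 else 0.0


def boundary_agreement(segmented, truth) -> BoundaryReport:
    """Mean IoU of nearest-centroid matched polygons, both directions.

    Sensitivity matches every truth cell to its nearest segmented cell;
    specificity matches every segmented cell to its nearest truth cell.
    """
    segmented, truth = list(segmented), list(truth)
    if not segmented or not truth:
        logger.warning("empty polygon set; boundary agreement scored 0")
        return BoundaryReport(0.0, 0.0)
    seg_tree = cKDTree(_centroids(segmented))
    tru_tree = cKDTree(_centroids(truth))
    _, nearest_seg = seg_tree.query(_centroids(truth))
    _, nearest_tru = tru_tree.query(_centroids(segmented))
    sens = float(np.mean([_iou(t, segmented[j]) for t, j in zip(truth, nearest_seg)]))
    spec = float(np.mean([_iou(s, truth[j]) for s, j in zip(segmented, nearest_tru)]))
    return BoundaryReport(sensitivity=sens, specificity=spec)


def roundness(poly) -> float:
    """R = 4 pi area / girth^2; 1 for a circle, pi/4 for a square."""
    return 4.0 * np.pi * poly.area / poly.length**2


def _curve_iou(x: np.ndarray, y: np.ndarray, grid_points: int = 512) -> float:
    """IoU of the areas under two kernel-density curves on a shared grid.

    Both curves use the same normal-reference bandwidth, computed from the
    pooled sample, so the comparison is bandwidth-symmetric.
    """
    pooled = np.concatenate([x, y])
    sd = pooled.std(ddof=1)
    if sd == 0:
        return 1.0
    if x.std(ddof=1) == 0 or y.std(ddof=1) == 0:
        # a degenerate (constant) sample: overlap iff the other sample
        # concentrates on the same value
        return 1.0 if np.allclose(x.mean(), y.mean()) else 0.0
    bw = 1.06 * sd * len(pooled) ** (-1 / 5)
    kx = gaussian_kde(x, bw_method=bw / x.std(ddof=1))
    ky = gaussian_kde(y, bw_method=bw / y.std(ddof=1))
    lo = pooled.min() - 3 * bw
    hi = pooled.max() + 3 * bw
    grid = np.linspace(lo, hi, grid_points)
    fx = kx(grid)
    fy = ky(grid)
    inter = np.trapezoid(np.minimum(fx, fy), grid)
    union = np.trapezoid(np.maximum(fx, fy), grid)
    return float(inter / union) if union > 0 else 0.0


def morphology_metrics(segmented, truth) -> dict[str, float]:
    """Density-curve IoUs of area, girth and roundness distributions."""
    segmented, truth = list(segmented), list(truth)
    if len(segmented) < 2 or len(truth) < 2:
        raise ValueError("need at least two polygons per set for densities")
    feats = {
        "area": (np.array([p.area for p in segmented]),
                 np.array([p.area for p in truth])),
        "girth": (np.array([p.length for p in segmented]),
                  np.array([p.length for p in truth])),
        "roundness": (np.array([roundness(p) for p in segmented]),
                      np.array([roundness(p) for p in truth])),
    }
    return {name: _curve_iou(a, b) for name, (a, b) in feats.items()}


def label_transfer(
    E: np.ndarray, reference: ReferencePanel, top: int = TOP_MATCHES
):
    """Transfer reference cell types to segmented cells.

    For each segmented cell the ``top`` most cosine-similar reference
    cells vote with their similarity, aggregated by type and normalised to
    a probability vector; ties resolve to the lexicographically first type.
    Returns (type labels, probability matrix over reference.types).
    """
    E = np.asarray(E, dtype=np.float64)
    S = reference.S
    ne = np.linalg.norm(E, axis=1, keepdims=True)
    ns = np.linalg.norm(S, axis=1, keepdims=True)
    ne[ne == 0] = 1.0
    ns[ns == 0] = 1.0
    cos = (E / ne) @ (S / ns).T
    top = min(top, S.shape[0])
    idx = np.argsort(-cos, axis=1, kind="stable")[:, :top]
    types = reference.types
    type_idx = np.array([types.index(t) for t in reference.cell_type])
    n = E.shape[0]
    probs = np.zeros((n, len(types)))
    sims = np.maximum(cos[np.arange(n)[:, None], idx], 0.0)
    np.add.at(probs, (np.repeat(np.arange(n), top), type_idx[idx].ravel()),
              sims.ravel())
    totals = probs.sum(axis=1, keepdims=True)
    uniform = totals[:, 0] == 0
    probs[uniform] = 1.0 / len(types)
    totals[totals == 0] = 1.0
    probs = probs / np.where(totals > 0, totals, 1.0)
    labels = np.array([types[j] for j in np.argmax(probs, axis=1)], dtype=object)
    return labels, probs


def imputation_benchmark(
    transcripts,
    reference,
    mask_fraction: float = 0.3,
    reps: int = 3,
    seed: int = 0,
    run_pipeline=None,
    **pipeline_kwargs,
):
    """Masked-gene imputation accuracy with a gene-shuffled null.

    Per repetition a random ``mask_fraction`` of the intersection genes is
    removed from the ST data, segmentation + imputation run on the rest,
    and the imputed masked-gene expression is scored against the reference
    (top-20 cosine / RMSE protocol).  The null shuffles the masked-gene
    columns of the imputed matrix.  ``run_pipeline(molecules_df, reference,
    seed=...)`` must return ``(E_like, imputed, gene_names)``; the default
    is the package's own end-to-end pipeline.

    Returns a list of dicts with keys ``sim_c``, ``sim_r``, ``null_sim_c``,
    ``masked_genes``.
    """
    if not 0.0 < mask_fraction < 1.0:
        raise ValueError("mask_fraction must lie strictly between 0 and 1")
    if run_pipeline is None:
        from .pipeline import _imputation_run
        run_pipeline = _imputation_run

    import pandas as pd

    if isinstance(transcripts, TranscriptTable):
        molecules = transcripts.to_frame()[["x", "y", "gene"]]
    else:
        molecules = transcripts[["x", "y", "gene"]]

    # intersection genes of the unmasked problem
    probe_table, probe_panel = encode_genes(molecules, reference)
    genes = np.array(probe_panel.gene_ids, dtype=object)
    rng = np.random.default_rng(seed)
    reports = []
    for rep in range(reps):
        n_mask = max(1, int(round(mask_fraction * len(genes))))
        masked = np.sort(rng.choice(len(genes), size=n_mask, replace=False))
        masked_genes = genes[masked]
        kept = molecules[~molecules["gene"].isin(masked_genes)]
        imputed, imputed_genes = run_pipeline(
            kept, reference, seed=int(rng.integers(2**31)), **pipeline_kwargs
        )
        gene_pos = {g: i for i, g in enumerate(imputed_genes)}
        cols = [gene_pos[g] for g in masked_genes if g in gene_pos]
        imp_masked = imputed[:, cols]
        ref_masked = probe_panel.S[:, masked]
        rep_report = expression_similarity_metrics(imp_masked, ref_masked)
        null = imp_masked[:, rng.permutation(imp_masked.shape[1])]
        null_report = expression_similarity_metrics(null, ref_masked)
        reports.append({
            "sim_c": float(rep_report.sim_c.mean()),
            "sim_r": float(rep_report.sim_r.mean()),
            "null_sim_c": float(null_report.sim_c.mean()),
            "masked_genes": [str(g) for g in masked_genes],
        })
    return reports
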