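"""End-to-end convenience layer: preprocess -> candidates -> training ->
final assignment -> polygons -> refinement -> imputation."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .candidates import CandidateSet, estimate_candidates
from .postprocess import (
    apply_nuclear_priors,
    impute_transcriptome,
    nuclear_pair_offsets,
    polygonal_boundaries,
    refine_assignments,
)
from .preprocess import (
    ReferencePanel,
    TranscriptTable,
    compute_noise_distance_scores,
    encode_genes,
)
from .train import (
    RunConfig,
    SegmentationResult,
    TrainedModel,
    final_assignment,
    run_training,
)

logger = logging.getLogger(__name__)

__all__ = ["PipelineResult", "segment"]


@dataclass
class PipelineResult:
    table: TranscriptTable
    reference: ReferencePanel
    candidates: CandidateSet
    model: TrainedModel
    raw_result: SegmentationResult  # before polygon refinement
    result: SegmentationResult  # after refinement
    polygons: dict
    degenerate_cells: list[int]


def segment(
    transcripts,
    reference,
    config: RunConfig | None = None,
    candidates: CandidateSet | None = None,
    nuclei=None,
    cell_radius: float = 6.5,
    marker_categories: int = 10,
    cell_type_key: str = "cell_type",
    top_genes: int | None = None,
    alpha: float | str | None = None,
    refine: bool = True,
) -> PipelineResult:
    """Run the full segmentation pipeline.

    ``transcripts`` is a DataFrame with x / y / gene columns (or an encoded
    :class:`TranscriptTable`); ``reference`` an AnnData or
    ``(counts, genes, cell_types)`` tuple.  Candidate centres are estimated
    from marker-gene density unless supplied (or derived from ``nuclei``
    polygons, which also switch the policy's location features to
    boundary distances and clip the final polygons against foreign nuclei).

    ``alpha`` controls the boundary detail of the cell polygons.  The
    default traces boundaries at the prior cell-radius scale
    (alpha = 1 / cell_radius), so molecule clusters far from the cell body
    fall outside the polygon and are reclassified as noise by the
    refinement step; pass 0 for convex hulls or ``"optimize"`` for the
    per-cell automatic search (which by construction covers every
    assigned molecule and therefore disables refinement).
    """
    config = config or RunConfig()
    if isinstance(transcripts, TranscriptTable) and transcripts.gene_code is not None:
        table = transcripts
        if isinstance(reference, ReferencePanel):
            panel = reference
        else:
            raise ValueError("encoded table requires a ReferencePanel")
    else:
        table, panel = encode_genes(
            transcripts, reference, cell_type_key=cell_type_key,
            top_genes=top_genes,
        )
    if table.nds is None:
        compute_noise_distance_scores(table, d=config.nds_d, q=config.q)

    if nuclei is not None:
        centers = np.array([[p.centroid.x, p.centroid.y] for p in nuclei])
        candidates = CandidateSet(centers, provenance="nuclear")
    elif candidates is None:
        candidates = estimate_candidates(
            table, panel, r=cell_radius, c=marker_categories, seed=config.seed
        )

    offsets_fn = None
    if nuclei is not None:
        offsets_fn = lambda tbl, nb: nuclear_pair_offsets(tbl, nuclei, nb)
    model = run_training(table, candidates, panel, config,
                         pair_offsets_fn=offsets_fn)
    raw = final_assignment(table, model)
    if alpha is None:
        alpha = 1.0 / cell_radius
    elif alpha == "optimize":
        alpha = None
    polygons, degenerate = polygonal_boundaries(table, raw, alpha=alpha)
    if nuclei is not None:
        polygons = apply_nuclear_priors(polygons, nuclei)
    result = refine_assignments(table, raw, polygons) if refine else raw
    return PipelineResult(
        table=table, reference=panel, candidates=candidates, model=model,
        raw_result=raw, result=result, polygons=polygons,
        degenerate_cells=degenerate,
    )


def _imputation_run(molecules: pd.DataFrame, reference, seed: int,
                    config: RunConfig | None = None, **kwargs):
    """Segmentation + imputation runner used by the masked-gene benchmark.

    Returns ``(imputed profiles over all reference genes, gene names)``.
    """
    cfg = config or RunConfig()
    from dataclasses import replace

    cfg = replace(cfg, seed=seed)
    out = segment(molecules, reference, config=cfg, **kwargs)
    imputed = impute_transcriptome(out.result.E, out.reference)
    return imputed, list(out.reference.all_genes)
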