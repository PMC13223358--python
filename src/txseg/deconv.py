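"""Reference-guided deconvolution of segmented-cell expression profiles.

For each cell type the reference cells are compressed into ``cs`` adaptive
"cell states" through a trainable weight matrix (softplus-activated, so
states stay strictly positive); a second trainable matrix mixes the pooled
states into a predicted expression profile PE_j for every candidate cell.
Fitting PE to the observed segmented-cell profiles E (cosine alignment
loss) lets the reference reshape itself to the spatial data — absorbing
batch effects — while the per-cell-per-gene residual ER feeds back into
the segmentation reward as the expression similarity score (ESS).
"""

from __future__ import annotations

import logging

import numpy as np

from .autodiff import Adam, Var
from .preprocess import ReferencePanel

logger = logging.getLogger(__name__)

__all__ = [
    "DeconvolutionModel",
    "similarity_and_residual",
    "alignment_loss",
    "expression_similarity_scores",
]

NOISE = 0  # noise flag convention shared with the policy module


class DeconvolutionModel:
    """Trainable W (per type, cs x n_i) and V (c x cs*t) matrices."""

    def __init__(
        self,
        reference: ReferencePanel,
        n_candidates: int,
        cs: int = 10,
        dropout: float = 0.1,
        lr: float = 0.002,
        rng: np.random.Generator | None = None,
    ):
        if cs < 1:
            raise ValueError("cs must be >= 1")
        rng = rng if rng is not None else np.random.default_rng(0)
        self.cs = cs
        self.dropout_rate = dropout
        self.types = []
        self.S_blocks: list[np.ndarray] = []
        for t in reference.types:
            cells = reference.cells_of_type(t)
            if len(cells) == 0:
                logger.warning("cell type %s has no reference cells; excluded", t)
                continue
            self.types.append(t)
            self.S_blocks.append(reference.S[cells])
        self.t = len(self.types)
        self.k = reference.k
        self.W = [
            Var(rng.normal(0.0, 1.0 / np.sqrt(S.shape[0]), size=(cs, S.shape[0])),
                requires_grad=True)
            for S in self.S_blocks
        ]
        self.V = Var(
            rng.normal(0.0, 1.0 / np.sqrt(cs * self.t), size=(n_candidates, cs * self.t)),
            requires_grad=True,
        )
        # optimiser state persists across outer epochs: the inner loop
        # continues training rather than re-initialising
        self.optimizer = Adam(self.params, lr=lr)

    @property
    def params(self) -> list[Var]:
        return self.W + [self.V]

    # -- forward ---------------------------------------------------------
    def reference_states(self, rng: np.random.Generator | None = None) -> Var:
        """S' of shape (cs*t) x k: per-type softplus(W_i S_i), concatenated."""
        blocks = [
            (W @ Var(S)).softplus().dropout(self.dropout_rate, rng)
            for W, S in zip(self.W, self.S_blocks)
        ]
        return Var.concat(blocks, axis=0)

    def predicted_expression(self, rng: np.random.Generator | None = None) -> Var:
        """PE = dropout(softplus(V S')) of shape c x k (strictly positive
        where dropout keeps entries)."""
        sp = self.reference_states(rng)
        if self.V.data.shape[1] != sp.data.shape[0]:
            raise ValueError(
                f"V has {self.V.data.shape[1]} columns but S' has "
                f"{sp.data.shape[0]} rows"
            )
        return (self.V @ sp).softplus().dropout(self.dropout_rate, rng)

    # -- fitting ----------------------------------------------------------
    def fit(self, E: np.ndarray, iters: int = 30,
            rng: np.random.Generator | None = None) -> list[float]:
        """Run ``iters`` alignment-loss minimisation steps against E."""
        E = np.asarray(E, dtype=np.float64)
        norm_e = np.linalg.norm(E, axis=1)
        nonzero = norm_e > 0
        safe_norm = np.where(nonzero, norm_e, 1.0)
        losses = []
        for _ in range(iters):
            pe = self.predicted_expression(rng)
            loss = _alignment_loss_var(pe, E, safe_norm, nonzero)
            self.optimizer.zero_grad()
            loss.backward()
            self.optimizer.step()
            losses.append(float(loss.data))
        return losses

    def residuals(self, E: np.ndarray):
        """Deterministic (dropout-off) PE, ES, ER against the profiles E."""
        pe = self.predicted_expression(rng=None).data
        es, er = similarity_and_residual(pe, E)
        return pe, es, er


def _alignment_loss_var(pe: Var, E: np.ndarray, safe_norm: np.ndarray,
                        nonzero: np.ndarray) -> Var:
    """(1/c) sum_j (1 - ES_j) as a graph node.

    Cells with an all-zero observed profile have ES defined as 0 and
    contribute a constant 1 with zero gradient.
    """
    dot = (pe * Var(E)).sum(axis=1)
    norm_pe = ((pe * pe).sum(axis=1) + 1e-30) ** 0.5
    es = dot / (norm_pe * Var(safe_norm))
    es = es * Var(nonzero.astype(float))
    return (1.0 - es).mean()


def similarity_and_residual(PE: np.ndarray, E: np.ndarray):
    """Cosine similarity ES_j and min-max residual ER_j per candidate cell.

    ER_j is |PE_j - E_j| rescaled to [0, 1] within cell j across genes;
    an all-equal residual row (and any empty cell) maps to zeros.
    """
    PE = np.asarray(PE, dtype=np.float64)
    E = np.asarray(E, dtype=np.float64)
    norm_pe = np.linalg.norm(PE, axis=1)
    norm_e = np.linalg.norm(E, axis=1)
    denom = norm_pe * norm_e
    with np.errstate(invalid="ignore", divide="ignore"):
        es = np.where(denom > 0, (PE * E).sum(axis=1) / np.where(denom > 0, denom, 1.0), 0.0)
    raw = np.abs(PE - E)
    lo = raw.min(axis=1, keepdims=True)
    hi = raw.max(axis=1, keepdims=True)
    span = hi - lo
    er = np.where(span > 0, (raw - lo) / np.where(span > 0, span, 1.0), 0.0)
    er[norm_e == 0] = 0.0  # empty cells are flagged by ES = 0, ER = 0
    return es, er


def alignment_loss(es: np.ndarray) -> float:
    """(1/c) sum_j (1 - ES_j); bounded in [0, 2]."""
    es = np.asarray(es, dtype=np.float64)
    return float(np.mean(1.0 - es))


def expression_similarity_scores(
    er: np.ndarray,
    cell_idx: np.ndarray,
    H: np.ndarray,
    gene_code: np.ndarray,
    neutral: float = 0.5,
) -> np.ndarray:
    """Per-molecule ESS from the residual matrix.

    A molecule of gene code kappa <= k assigned to cell j scores
    ER[j, kappa] when flagged noise and 1 - ER[j, kappa] otherwise;
    out-of-panel molecules (code k+1) receive the neutral score so their
    reward depends only on density and proximity.
    """
    er = np.asarray(er, dtype=np.float64)
    k = er.shape[1]
    gene_code = np.asarray(gene_code)
    in_panel = gene_code <= k
    ess = np.full(gene_code.shape[0], neutral, dtype=np.float64)
    rows = np.asarray(cell_idx)[in_panel]
    cols = gene_code[in_panel] - 1
    vals = er[rows, cols]
    noise_mask = np.asarray(H)[in_panel] == NOISE
    ess[in_panel] = np.where(noise_mask, vals, 1.0 - vals)
    return ess
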