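"""The policy-gradient segmentation model.

Transcript-to-cell assignment is cast as a reinforcement-learning problem:
for every molecule the policy scores its m nearest candidate cells through
a multi-modal network (candidate embedding + gene embedding + relative-
location features, fused after layer normalisation) and holds a separate
binary noise head initialised from the noise distance scores.  Actions
(cell choice G, noise flag H) are sampled from the resulting categorical
distributions; the REINFORCE loss weights the log-probabilities of the
sampled actions by a per-molecule reward combining local density (NDS),
proximity to the assigned cell centre (CDS) and expression agreement (ESS).
"""

from __future__ import annotations

import logging

import numpy as np
from scipy.spatial import cKDTree

from .autodiff import Var
from .candidates import CandidateSet
from .preprocess import TranscriptTable, quantile

logger = logging.getLogger(__name__)

__all__ = [
    "PolicyParameters",
    "nearest_candidate_cells",
    "assignment_probabilities",
    "noise_probabilities",
    "sample_assignments",
    "center_distance_scores",
    "compute_rewards",
    "region_loss",
]

LOG_FLOOR = 1e-12  # probability clamp at sampled actions

NOISE, NON_NOISE = 0, 1  # noise-head column convention


class PolicyParameters:
    """Trainable state of the segmentation policy.

    ``f``: candidate-cell embeddings (c x p); ``g``: gene embeddings
    ((k+1) x p, one row per gene code including the out-of-panel code);
    a two-affine location net mapping the 2-D molecule-candidate offset to
    p dims; a three-affine fusion net mapping the fused p-vector to one
    logit; ``noise``: per-molecule noise logits (n x 2) initialised to
    (1 - NDS, NDS).  All hidden widths equal the embedding width p.
    """

    def __init__(
        self,
        n_candidates: int,
        k: int,
        nds: np.ndarray,
        p: int = 20,
        dropout: float = 0.1,
        offset_scale: float = 6.5,
        rng: np.random.Generator | None = None,
    ):
        rng = rng if rng is not None else np.random.default_rng(0)
        self.p = p
        self.dropout_rate = dropout
        # offsets are fed in cell-radius units; with a random first-layer
        # bias the rectifier pattern then encodes offset magnitude, which
        # would otherwise be cancelled by the per-pair layer normalisation
        self.offset_scale = offset_scale

        def he(shape):
            fan_in = shape[0]
            return Var(rng.normal(0.0, np.sqrt(2.0 / fan_in), size=shape),
                       requires_grad=True)

        self.f = Var(rng.normal(size=(n_candidates, p)), requires_grad=True)
        self.g = Var(rng.normal(size=(k + 1, p)), requires_grad=True)
        self.loc_W1 = he((2, p))
        self.loc_b1 = Var(rng.normal(0.0, 1.0, size=p), requires_grad=True)
        self.loc_W2, self.loc_b2 = he((p, p)), Var(np.zeros(p), requires_grad=True)
        self.fus_W1, self.fus_b1 = he((p, p)), Var(np.zeros(p), requires_grad=True)
        self.fus_W2, self.fus_b2 = he((p, p)), Var(np.zeros(p), requires_grad=True)
        self.fus_W3, self.fus_b3 = he((p, 1)), Var(np.zeros(1), requires_grad=True)
        nds = np.asarray(nds, dtype=np.float64)
        self.noise = Var(np.column_stack([1.0 - nds, nds]), requires_grad=True)

    @property
    def network_params(self) -> list[Var]:
        """Everything except the noise logits (which have their own lr)."""
        return [
            self.f, self.g,
            self.loc_W1, self.loc_b1, self.loc_W2, self.loc_b2,
            self.fus_W1, self.fus_b1, self.fus_W2, self.fus_b2,
            self.fus_W3, self.fus_b3,
        ]

    @property
    def all_params(self) -> list[Var]:
        return self.network_params + [self.noise]

    # -- forward pieces --------------------------------------------------
    def pair_logits(
        self,
        offsets: np.ndarray,
        cand_idx: np.ndarray,
        gene_code: np.ndarray,
        rng: np.random.Generator | None = None,
    ) -> Var:
        """Assignment logits for a batch: offsets (B, m, 2) -> (B, m).

        ``rng`` enables dropout (training); None runs deterministically.
        """
        B, m, _ = offsets.shape
        scaled = offsets / self.offset_scale
        h = (Var(scaled) @ self.loc_W1 + self.loc_b1).relu() @ self.loc_W2 + self.loc_b2
        fe = self.f.gather(cand_idx)  # (B, m, p)
        ge = self.g.gather(np.asarray(gene_code) - 1).layer_norm().reshape(B, 1, self.p)
        fused = (fe.layer_norm() + ge + h.layer_norm()).dropout(self.dropout_rate, rng)
        x = (fused @ self.fus_W1 + self.fus_b1).relu()
        x = (x @ self.fus_W2 + self.fus_b2).relu()
        logits = (x @ self.fus_W3 + self.fus_b3).reshape(B, m)
        if not np.isfinite(logits.data).all():
            raise FloatingPointError(
                "non-finite assignment logits; parameter scale diagnostics: "
                + ", ".join(f"{np.abs(v.data).max():.3g}" for v in self.network_params)
            )
        return logits.dropout(self.dropout_rate, rng)  # dropout before softmax

    def noise_logits(self, idx: np.ndarray) -> Var:
        return self.noise.gather(idx)


def nearest_candidate_cells(
    table: TranscriptTable, candidates: CandidateSet, m: int = 8
) -> np.ndarray:
    """Indices (n x m) of each molecule's m nearest candidate centres.

    Euclidean distance, ties broken by lower candidate index.
    """
    c = len(candidates)
    if c < m:
        logger.warning("only %d candidates for m=%d neighbors; lowering m", c, m)
        m = c
    pts = table.coords
    centers = candidates.centers
    if c <= 4096:
        # exact, stable tie-break by index
        d = ((pts[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        return np.argsort(d, axis=1, kind="stable")[:, :m]
    tree = cKDTree(centers)
    _, idx = tree.query(pts, k=m)
    return np.atleast_2d(idx)


def assignment_probabilities(
    params: PolicyParameters,
    table: TranscriptTable,
    neighbor_idx: np.ndarray,
    centers: np.ndarray,
    rng: np.random.Generator | None = None,
    offsets: np.ndarray | None = None,
    subset: np.ndarray | None = None,
) -> tuple[np.ndarray, Var]:
    """Per-molecule assignment probabilities over the m nearest candidates.

    Returns ``(C_prob, logits)`` where ``C_prob`` rows are simplexes and
    ``logits`` is the differentiable graph node.  ``offsets`` overrides the
    default molecule-minus-centre offsets (used by the nuclear-prior mode).
    """
    idx = np.arange(len(table)) if subset is None else subset
    nb = neighbor_idx[idx]
    if offsets is None:
        offsets = table.coords[idx][:, None, :] - centers[nb]
    logits = params.pair_logits(offsets, nb, table.gene_code[idx], rng)
    c_prob = np.exp(logits.log_softmax(axis=-1).data)
    return c_prob, logits


def noise_probabilities(
    params: PolicyParameters, subset: np.ndarray | None = None
) -> tuple[np.ndarray, Var]:
    """Binary noise probabilities (column 0 = noise, column 1 = non-noise)."""
    logits = params.noise if subset is None else params.noise_logits(subset)
    return np.exp(logits.log_softmax(axis=-1).data), logits


def sample_assignments(
    c_prob: np.ndarray, n_prob: np.ndarray, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sample (G, H): neighbour-slot choice and noise flag per molecule."""
    G = _sample_rows(c_prob, rng)
    H = _sample_rows(n_prob, rng)
    return G, H


def _sample_rows(prob: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    cum = np.cumsum(prob, axis=1)
    cum /= cum[:, -1:]
    u = rng.random(prob.shape[0])
    return np.minimum((cum < u[:, None]).sum(axis=1), prob.shape[1] - 1)


def center_distance_scores(
    coords: np.ndarray,
    assigned_centers: np.ndarray,
    q: float = 0.999,
) -> np.ndarray:
    """CDS_i = max(0, 1 - g_i / Q(g, q)) within the batch.

    ``g_i`` is the distance from molecule i to the centre of its assigned
    cell (centres estimated by averaging assigned molecule coordinates).
    A degenerate batch with Q = 0 scores 1 everywhere, mirroring NDS.
    """
    g = np.linalg.norm(coords - assigned_centers, axis=1)
    Q = quantile(g, q)
    if Q == 0.0:
        return np.ones_like(g)
    return np.maximum(0.0, 1.0 - g / Q)


def compute_rewards(
    nds: np.ndarray,
    cds: np.ndarray,
    ess: np.ndarray,
    H: np.ndarray,
    orientation: str = "isolation",
) -> np.ndarray:
    """Multiplicative reward NDS x CDS x ESS with a noise-branch switch.

    ``orientation="isolation"`` (default): a noise call is weighted by
    (1 - NDS) — isolated molecules are rewarded for being called noise —
    and a cell assignment by NDS.  ``orientation="density"`` swaps the two
    branches (the alternative printed reading).
    """
    nds = np.asarray(nds, dtype=np.float64)
    noise_mask = np.asarray(H) == NOISE
    if orientation == "isolation":
        w = np.where(noise_mask, 1.0 - nds, nds)
    elif orientation == "density":
        w = np.where(noise_mask, nds, 1.0 - nds)
    else:
        raise ValueError(f"unknown reward orientation {orientation!r}")
    return w * np.asarray(cds) * np.asarray(ess)


def region_loss(
    reward: np.ndarray,
    c_prob: Var | np.ndarray,
    n_prob: Var | np.ndarray,
    G: np.ndarray,
    H: np.ndarray,
) -> Var:
    """REINFORCE loss: -(1/n) sum_i reward_i (ln P(G_i) + ln P(H_i)).

    Probabilities at sampled actions are clamped at 1e-12 before the log.
    Differentiable when the probability inputs are graph nodes.
    """
    c_prob = c_prob if isinstance(c_prob, Var) else Var(np.asarray(c_prob, dtype=float))
    n_prob = n_prob if isinstance(n_prob, Var) else Var(np.asarray(n_prob, dtype=float))
    if (c_prob.data[np.arange(len(G)), G] <= LOG_FLOOR).any() or (
        n_prob.data[np.arange(len(H)), H] <= LOG_FLOOR
    ).any():
        logger.warning("zero probability at a sampled action; clamped at %g", LOG_FLOOR)
    lp_g = c_prob.take_along(np.asarray(G)).clip_min(LOG_FLOOR).log()
    lp_h = n_prob.take_along(np.asarray(H)).clip_min(LOG_FLOOR).log()
    return -((Var(np.asarray(reward, dtype=float)) * (lp_g + lp_h)).mean())
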