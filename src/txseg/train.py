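"""Alternating training loop between segmentation and deconvolution.

Each epoch: molecules are shuffled into batches (n / batch_divisor, capped),
actions are sampled from the current policy, rewards are computed from NDS,
the batch-quantile centre distance score (CDS) and the previous epoch's
expression residuals (ESS), and the REINFORCE loss is minimised.  The
deconvolution model is then trained for a fixed number of inner iterations
against the epoch's aggregated profiles and refreshes the residuals used in
the next epoch's rewards.  A final deterministic pass (dropout off, argmax
instead of sampling) produces the segmentation result.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .autodiff import Adam
from .candidates import CandidateSet
from .deconv import DeconvolutionModel, expression_similarity_scores
from .policy import (
    NOISE,
    NON_NOISE,
    PolicyParameters,
    assignment_probabilities,
    center_distance_scores,
    compute_rewards,
    nearest_candidate_cells,
    noise_probabilities,
    region_loss,
    sample_assignments,
)
from .preprocess import ReferencePanel, TranscriptTable, compute_noise_distance_scores

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "TrainedModel", "SegmentationResult",
           "initialize_assignments", "run_training", "final_assignment"]


@dataclass
class RunConfig:
    """Hyper-parameters of a segmentation run (defaults are the method's)."""

    epochs: int = 500
    m: int = 8  # nearest candidate cells per molecule
    p: int = 20  # embedding / hidden width
    dropout: float = 0.1
    cs: int = 10  # deconvolution cell states per type
    inner_iters: int = 30  # deconvolution steps per epoch
    lr_noise: float = 0.01
    lr_other: float = 0.002
    lr_decay: float = 0.996  # multiplicative, per epoch
    batch_divisor: int = 50
    batch_cap: int = 2_000_000
    nds_d: int = 100  # neighbours for the noise distance score
    q: float = 0.999  # quantile for NDS and CDS (0.9999 for spot data)
    offset_scale: float = 6.5  # prior cell radius r (um); offsets are fed
    # to the location net in units of r
    reward_orientation: str = "isolation"
    ablate_noise_sampling: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.epochs < 0:
            raise ValueError("epochs must be >= 0")
        if not 0.0 < self.lr_decay <= 1.0:
            raise ValueError("lr_decay must lie in (0, 1]")


@dataclass
class TrainedModel:
    policy: PolicyParameters
    deconv: DeconvolutionModel
    candidates: CandidateSet
    neighbor_idx: np.ndarray
    config: RunConfig
    centers_est: np.ndarray  # running per-candidate centre estimates
    er: np.ndarray  # latest expression residual matrix (c x k)
    region_losses: list[float] = field(default_factory=list)
    alignment_losses: list[float] = field(default_factory=list)
    pair_offsets: np.ndarray | None = None  # nuclear-prior override (n x m x 2)


@dataclass
class SegmentationResult:
    """Per-molecule labels and per-cell profiles of the final pass."""

    cell: np.ndarray  # candidate index per molecule
    noise: np.ndarray  # boolean noise flag per molecule
    E: np.ndarray  # candidates x k counts over non-noise molecules
    candidates: CandidateSet

    @property
    def assigned_mask(self) -> np.ndarray:
        return ~self.noise

    @property
    def n_recovered_cells(self) -> int:
        """Candidates that received at least one non-noise molecule."""
        return len(np.unique(self.cell[~self.noise]))

    def assignment_rate(self) -> float:
        return float((~self.noise).mean())


def aggregate_expression(
    cell_idx: np.ndarray, noise: np.ndarray, gene_code: np.ndarray,
    n_candidates: int, k: int,
) -> np.ndarray:
    """Candidate x gene counts over non-noise, in-panel molecules."""
    E = np.zeros((n_candidates, k))
    keep = (~noise) & (gene_code <= k)
    np.add.at(E, (cell_idx[keep], gene_code[keep] - 1), 1.0)
    return E


def _estimate_centers(
    coords: np.ndarray, cell_idx: np.ndarray, noise: np.ndarray,
    fallback: np.ndarray,
) -> np.ndarray:
    """Per-candidate mean coordinate of its non-noise molecules; candidates
    without molecules keep their previous centre."""
    c = fallback.shape[0]
    sums = np.zeros((c, 2))
    counts = np.zeros(c)
    keep = ~noise
    np.add.at(sums, cell_idx[keep], coords[keep])
    np.add.at(counts, cell_idx[keep], 1.0)
    centers = fallback.copy()
    has = counts > 0
    centers[has] = sums[has] / counts[has, None]
    return centers


def initialize_assignments(
    table: TranscriptTable,
    candidates: CandidateSet,
    deconv: DeconvolutionModel,
    neighbor_idx: np.ndarray,
):
    """Nearest-candidate assignment, all molecules non-noise.

    Returns (cell_idx, noise, E, ES, ER, ESS) — the state the first epoch
    trains against.
    """
    cell_idx = neighbor_idx[:, 0]
    noise = np.zeros(len(table), dtype=bool)
    E = aggregate_expression(cell_idx, noise, table.gene_code,
                             len(candidates), deconv.k)
    _, es, er = deconv.residuals(E)
    ess = expression_similarity_scores(
        er, cell_idx, np.full(len(table), NON_NOISE), table.gene_code
    )
    return cell_idx, noise, E, es, er, ess


def run_training(
    table: TranscriptTable,
    candidates: CandidateSet,
    reference: ReferencePanel,
    config: RunConfig | None = None,
    pair_offsets_fn=None,
) -> TrainedModel:
    """Train the policy and deconvolution models; returns the trained state
    with per-epoch loss traces."""
    config = config or RunConfig()
    rng = np.random.default_rng(config.seed)
    init_rng = np.random.default_rng(rng.integers(2**31))
    sample_rng = np.random.default_rng(rng.integers(2**31))
    dropout_rng = np.random.default_rng(rng.integers(2**31))
    shuffle_rng = np.random.default_rng(rng.integers(2**31))

    if table.gene_code is None:
        raise ValueError("transcript table must be gene-encoded first")
    if table.nds is None:
        compute_noise_distance_scores(table, d=config.nds_d, q=config.q)

    n = len(table)
    neighbor_idx = nearest_candidate_cells(table, candidates, m=config.m)
    policy = PolicyParameters(
        len(candidates), reference.k, table.nds,
        p=config.p, dropout=config.dropout,
        offset_scale=config.offset_scale, rng=init_rng,
    )
    deconv = DeconvolutionModel(
        reference, len(candidates), cs=config.cs, dropout=config.dropout,
        lr=config.lr_other, rng=init_rng,
    )
    opt_net = Adam(policy.network_params, lr=config.lr_other)
    opt_noise = Adam([policy.noise], lr=config.lr_noise)

    cell_idx, noise, E, es, er, _ = initialize_assignments(
        table, candidates, deconv, neighbor_idx
    )
    centers_est = _estimate_centers(table.coords, cell_idx, noise,
                                    candidates.centers)
    model = TrainedModel(
        policy=policy, deconv=deconv, candidates=candidates,
        neighbor_idx=neighbor_idx, config=config, centers_est=centers_est,
        er=er,
    )
    if pair_offsets_fn is not None:
        model.pair_offsets = pair_offsets_fn(table, neighbor_idx)

    nds = table.nds
    reward_nds = np.ones_like(nds) if config.ablate_noise_sampling else nds
    batch_size = min(config.batch_cap, max(1, int(np.ceil(n / config.batch_divisor))))

    for epoch in range(config.epochs):
        decay = config.lr_decay ** epoch
        opt_net.lr = config.lr_other * decay
        opt_noise.lr = config.lr_noise * decay
        deconv.optimizer.lr = config.lr_other * decay

        perm = shuffle_rng.permutation(n)
        epoch_cell = np.empty(n, dtype=np.int64)
        epoch_noise = np.zeros(n, dtype=bool)
        batch_losses = []
        for start in range(0, n, batch_size):
            idx = perm[start:start + batch_size]
            offsets = (
                model.pair_offsets[idx] if model.pair_offsets is not None else None
            )
            c_prob_np, logits = assignment_probabilities(
                policy, table, neighbor_idx, candidates.centers,
                rng=dropout_rng, offsets=offsets, subset=idx,
            )
            c_prob = logits.log_softmax(axis=-1).exp()
            if config.ablate_noise_sampling:
                H = np.full(len(idx), NON_NOISE)
                G = _sample_from(c_prob.data, sample_rng)
            else:
                n_prob_np, n_logits = noise_probabilities(policy, subset=idx)
                n_prob = n_logits.log_softmax(axis=-1).exp()
                G, H = sample_assignments(c_prob.data, n_prob_np, sample_rng)
            assigned = neighbor_idx[idx, G]
            cds = center_distance_scores(
                table.coords[idx], centers_est[assigned], q=config.q
            )
            ess = expression_similarity_scores(
                model.er, assigned, H, table.gene_code[idx]
            )
            reward = compute_rewards(
                reward_nds[idx], cds, ess, H,
                orientation=config.reward_orientation,
            )
            if config.ablate_noise_sampling:
                loss = region_loss(reward, c_prob, _const_nonnoise(len(idx)), G, H)
            else:
                loss = region_loss(reward, c_prob, n_prob, G, H)
            if not np.isfinite(loss.data):
                raise FloatingPointError(
                    f"non-finite region loss at epoch {epoch}"
                )
            opt_net.zero_grad()
            opt_noise.zero_grad()
            loss.backward()
            opt_net.step()
            opt_noise.step()
            batch_losses.append(float(loss.data))
            epoch_cell[idx] = assigned
            epoch_noise[idx] = H == NOISE

        centers_est = _estimate_centers(
            table.coords, epoch_cell, epoch_noise, centers_est
        )
        model.centers_est = centers_est
        E = aggregate_expression(
            epoch_cell, epoch_noise, table.gene_code, len(candidates), deconv.k
        )
        inner = deconv.fit(E, iters=config.inner_iters, rng=dropout_rng)
        _, es, model.er = deconv.residuals(E)
        model.region_losses.append(float(np.mean(batch_losses)))
        model.alignment_losses.append(inner[-1] if inner else float("nan"))

    return model


def _sample_from(prob, rng):
    cum = np.cumsum(prob, axis=1)
    cum /= cum[:, -1:]
    u = rng.random(prob.shape[0])
    return np.minimum((cum < u[:, None]).sum(axis=1), prob.shape[1] - 1)


def _const_nonnoise(b: int):
    out = np.zeros((b, 2))
    out[:, NON_NOISE] = 1.0
    return out


def final_assignment(
    table: TranscriptTable, model: TrainedModel, chunk: int = 50_000
) -> SegmentationResult:
    """Deterministic pass: dropout off, argmax of both heads.

    Argmax ties resolve to the lower neighbour index (and, for the noise
    head, to the noise class).
    """
    n = len(table)
    config = model.config
    cell = np.empty(n, dtype=np.int64)
    noise = np.zeros(n, dtype=bool)
    for start in range(0, n, chunk):
        idx = np.arange(start, min(start + chunk, n))
        offsets = (
            model.pair_offsets[idx] if model.pair_offsets is not None else None
        )
        c_prob, _ = assignment_probabilities(
            model.policy, table, model.neighbor_idx, model.candidates.centers,
            rng=None, offsets=offsets, subset=idx,
        )
        G = np.argmax(c_prob, axis=1)
        cell[idx] = model.neighbor_idx[idx, G]
        if not config.ablate_noise_sampling:
            n_prob, _ = noise_probabilities(model.policy, subset=idx)
            noise[idx] = np.argmax(n_prob, axis=1) == NOISE
    E = aggregate_expression(cell, noise, table.gene_code,
                             len(model.candidates), model.deconv.k)
    return SegmentationResult(cell=cell, noise=noise, E=E,
                              candidates=model.candidates)
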