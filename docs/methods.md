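# Methods

## Problem setting

Input is (a) a molecule table from an imaging-based spatial
transcriptomics experiment — one record per detected mRNA with 2-D
coordinates in micrometers and a gene label — and (b) an scRNA-seq
reference with per-cell type annotations. Genes present in both (the
*intersection genes*, coded 1..k in lexicographic order; everything else
k+1) carry the expression signal. The task is to partition molecules into
cells plus background noise such that per-cell profiles resemble real
cells of the reference, and then to impute whole-transcriptome profiles
for the segmented cells. Any z coordinate in the input is ignored; the
model is strictly 2-D.

## Preprocessing

The noise distance score of molecule *i* is
`NDS_i = max(0, 1 − d_i / Q_q(d))` with *d_i* the mean Euclidean distance
to its *d* = 100 nearest neighbours (k-d tree; the molecule itself is
excluded — including it would inflate density uniformly) and *Q_q* the
*q* = 0.999 empirical quantile. All quantiles in the package use linear
interpolation between order statistics (NumPy's default), fixed across
NDS, CDS and the node cutoffs so the scores are reproducible. If all
molecules are coincident (Q = 0), NDS is defined as 1. For
sequencing-based spot data every count unit becomes one molecule at its
spot's coordinates, the panel is capped to the most highly expressed
intersection genes (2000 at production scale), and *q* is raised to
0.9999 because duplicate coordinates compress the low distance quantiles.

## Candidate estimation

1. **Marker scoring.** The reference is count-normalised per cell to a
   fixed total of 10⁴, averaged per type to `A` (genes × types), and
   `P = A / rowsum(A)`; the score is `S = ln(A + 1) · P` (natural log
   throughout). The top *p* = 3 genes per type, deduplicated in type
   order, form the marker list.
2. **Grid features.** A grid with spacing 2r spans the molecule bounding
   box (r = prior cell radius, default 6.5 µm at Xenium-like resolution).
   Each node counts each marker's molecules within 2r/π; columns (nodes)
   are standardised, and markers are clustered into *c* categories by
   average-linkage agglomerative clustering on 1 − Pearson correlation of
   their node profiles. Per category, a threshold t_c sums each member
   gene's maximum type-mean expression.
3. **Valid nodes and clustering.** Per category, each node's molecule
   count h (within one grid spacing, 2r — see "Design choices") defines
   cutoff₁ = Q₀.₉(h) × 0.01 and cutoff₂ = mean of h over nodes above
   cutoff₁; nodes with h > cutoff₂ (strict) are valid. The category's
   molecules within 2r of a valid node are grouped by DBSCAN (eps = 2r,
   min_samples = 3) and each group of size h is split into
   `k = max(1, int(0.25 · h · ln(max_t / t_c + 1)))` K-means clusters
   whose mean coordinates become candidate centres. MeanShift with
   bandwidth r/5 merges the pooled per-category centres.

Candidates may instead be supplied externally (a CSV of centres, or
nuclear polygons whose centroids seed the model).

## Segmentation policy

Each molecule considers its *m* = 8 nearest candidate centres. Per pair:
an offset-based location feature `h = Linear(ReLU(Linear(offset)))`, a
candidate embedding f_j and a gene embedding g; all three are layer-
normalised over the feature dimension (p = 20, also the hidden width of
every affine map), summed, passed through dropout (rate 0.1) and a
three-affine rectifier stack to one logit; a softmax over the m logits
gives C_prob (dropout is applied to the logits *before* the softmax so
rows remain probability vectors). The noise head holds per-molecule
trainable logits initialised to (1 − NDS, NDS).

Offsets enter the location net in units of r, and the first-layer bias is
randomly initialised. This matters: with zero biases the location net is
exactly linear in the offset, and per-pair layer normalisation then
cancels the offset's magnitude — the policy would see only direction and
degenerate into global candidate-popularity learning (observed as
assignment precision collapsing far below the nearest-candidate
baseline). The scaled input plus random bias makes the rectifier pattern
encode distance while keeping the published architecture.

**Rewards.** Sampled actions earn
`reward_i = w(NDS_i) · CDS_i · ESS_i`, where
`CDS_i = max(0, 1 − g_i / Q_q(g))` is computed per batch from the
distance to the assigned cell's centre (centres are running means of the
molecules assigned in the previous epoch, falling back to the candidate
location), and ESS comes from the deconvolution residual (below). The
noise-branch weight `w` is (1 − NDS) for a noise call and NDS for a cell
assignment (`reward_orientation="isolation"`, the default): isolated
molecules are rewarded for being called background, dense ones for being
assigned. The mirrored orientation is available as `"density"`. The
default was chosen because the mirrored form simultaneously (a)
contradicts the score's construction — low NDS marks isolation — and (b)
makes the noise-sampling ablation (NDS ≡ 1, all molecules non-noise)
yield identically zero rewards, i.e. no training at all, which cannot
reproduce the ablation's intended behaviour of an otherwise-unchanged
model.

**Loss.** `region_loss = −(1/n) Σ reward_i [ln P(G_i) + ln P(H_i)]`,
with probabilities at sampled actions clamped at 1e-12. Batches are the
molecule count divided by 50, capped at 2,000,000, reshuffled each epoch;
the CDS quantile is per batch.

## Deconvolution

Per type *i* with n_i reference cells, `S'_i = Dropout(Softplus(W_i S_i))`
with trainable `W_i` (cs × n_i, cs = 10 states per type); the row-wise
concatenation S' feeds `PE = Dropout(Softplus(V S'))` with trainable `V`
(candidates × cs·t). The alignment loss `(1/c) Σ_j (1 − cos(PE_j, E_j))`
is minimised for 30 Adam iterations per epoch against the epoch's
aggregated non-noise profiles E; optimiser state persists across epochs
(the inner loop continues training rather than restarting). Cells with
empty E have ES defined as 0 and zero gradient. The residual
`ER_j = minmax_j(|PE_j − E_j|)` is rescaled per cell across genes (an
all-equal row maps to zeros), and molecule *i* assigned to cell *j* with
gene code κ ≤ k gets `ESS_i = ER_{j,κ}` when flagged noise and
`1 − ER_{j,κ}` otherwise; out-of-panel molecules (code k+1) get the
neutral value 0.5 so their reward depends only on geometry and density.

## Training schedule and final pass

Adam throughout; initial learning rates 0.01 (noise logits) and 0.002
(all other parameters, including W and V), both decayed ×0.996 per epoch;
500 epochs at production scale. Initialisation assigns every molecule to
its nearest candidate, non-noise. The final pass disables dropout and
takes argmaxes (ties to the lower neighbour index; a tied noise head
resolves to noise). Conservation holds exactly: every molecule is either
in exactly one cell's profile or noise, per gene.

## Postprocessing

Cell polygons are alpha shapes of each cell's assigned molecules:
Delaunay triangles with circumradius ≥ 1/α are discarded and the rest
unioned (α = 0 is the convex hull; if the kept triangles are
disconnected, the largest component is the cell body). The pipeline
default is α = 1/r — boundary detail at the prior cell-radius scale —
so molecule clusters far from the cell body fall outside the polygon.
An automatic per-cell α (bisection over the observed circumradii for the
tightest single polygon touching every point) is available, but because
it covers every assigned molecule by construction it turns the
refinement step into a no-op; the radius-scale default is what gives
refinement its effect. Cells with fewer than three non-collinear
molecules are flagged degenerate and keep their counts but get no
polygon. Refinement reclassifies molecules outside their own cell's
polygon as noise (no reassignment to other cells — conservative, keeps
polygons consistent) and re-aggregates profiles; on the synthetic
fixture this prunes most molecules that seeding errors had attached to
the wrong cell, which is visible as a several-point precision gain.

Imputation: `A = cos(ln(1+E), ln(1+S))` over intersection genes; each
segmented cell's r = 40 most similar reference cells define occurrences
O_j and occurrence scores `OS_j = ln(n / O_j)` (a reference cell matched
by every segmented cell contributes nothing; a rarely-matched one is
up-weighted). Chosen weights similarity × OS are sorted descending, the
top k = 20 renormalised to sum one, and the reference cells' full
transcriptomes averaged — every imputed profile is a convex combination
of reference profiles. All-zero weight rows fall back to uniform weights
with a warning.

With nuclear priors, the policy's offset becomes the vector from the
nearest point of the candidate nucleus's boundary to the molecule (zero
inside; a molecule inside several overlapping nuclei keeps zero only for
the nearest-centroid one), and each final polygon has foreign nuclear
regions subtracted before being unioned with its own nucleus (if the
union is disconnected, the piece holding the nucleus is kept).

## Evaluation layer

* **Expression similarity**: cell totals scaled to the number of
  intersection genes; per segmented cell, SIM_C is the mean of its 20
  highest cosines against reference cells and SIM_R the mean of its 20
  lowest RMSEs.
* **Boundary agreement**: nearest-centroid matching (cheap and
  deterministic; "nearest" could alternatively mean maximal overlap),
  mean polygon IoU in both directions (sensitivity: truth → segmented;
  specificity: segmented → truth).
* **Morphology**: kernel densities of area, girth and roundness
  `R = 4πs/c²`; one normal-reference bandwidth (1.06·σ·n^(−1/5)) computed
  from the pooled sample is applied to both curves so the IoU of the two
  density curves is bandwidth-symmetric, evaluated on a shared grid.
* **Masked-gene imputation**: 30% of intersection genes are removed from
  the ST data, the pipeline reruns on the remainder, and imputed
  masked-gene profiles are scored against the reference (3 repetitions);
  the null shuffles the masked-gene columns of the imputed matrix.
* **Label transfer**: top-20 cosine-similar reference cells vote with
  their similarity, aggregated by type and normalised; ties resolve
  lexicographically.

## Synthetic tissue generator

The generator emulates exactly the structure the method exploits: shared
type profiles between tissue and reference, spatial cell bodies, and
uniform background. Per type, a sparse background programme (log-normal
magnitudes shared across types, mildly modulated per type with σ = 0.4)
plus `markers_per_type = 3` exclusive marker genes carrying
`marker_weight = 7.5%` of the simplex. Background expression is
deliberately *shared* across types: fully independent per-type
backgrounds would create accidental high-abundance type-exclusive genes
that no curated reference would call markers, distorting both marker
selection and the K-means split heuristic. Cell centres sit on a jittered
grid with minimum spacing 4r (jitter ±r/2); per-cell transcript counts
are Poisson(100); positions are isotropic Gaussian with sd r/2; noise
molecules are uniform over the field with ambient (tissue-mean) gene
frequencies at 5% of all molecules. Reference cells are multinomial draws
(50 per type, library size 1000).

The default fixture (200 cells, 8 types, 100 genes, ~21k molecules,
r = 6.5 µm, seed-controlled) runs end-to-end in under a minute per
50-epoch training on one CPU core; 50 epochs (a tenth of the production
default) is the fixture's training length and suffices for the loss
traces to flatten at this scale. Because cells are well separated by
construction, nearest-candidate assignment of cell molecules is already
nearly perfect; what the benchmark exercises on top of geometry is noise
handling (the baseline has none), candidate recovery, label transfer and
imputation. Passing it does not demonstrate robustness to overlapping
cells, anisotropic shapes, segmentation-scale density gradients, or real
batch effects between platforms.

## Numerical and design choices

* Float64 NumPy throughout with an in-package reverse-mode autodiff core;
  training is bitwise reproducible for a fixed seed on CPU. Gradients of
  both losses are validated against central finite differences.
* The per-node count radius for valid-node selection is one grid spacing
  (2r), while grid *features* use the stated 2r/π; a 2r/π disk on a 2r
  grid covers only ~32% of the plane and would make cells midway between
  nodes invisible.
* DBSCAN min_samples = 3 (a cell contributes only a handful of molecules
  per marker category; the valid-node prefilter already suppresses stray
  background).
* K-means/MeanShift randomness is tied to the run seed; agglomerative
  clustering and DBSCAN are deterministic.
* In the K-means split formula, h is the DBSCAN group size and max_t the
  maximum over category thresholds.
* Hidden widths equal the embedding width p; dropout rate 0.1 everywhere
  (policy fusion, logits, deconvolution), configurable as one rate.
* Degenerate guards: coincident batches give CDS ≡ 1 (mirroring NDS);
  all-equal residual rows give ER ≡ 0; empty categories and empty cells
  warn rather than fail.

## Limitations

* 2-D only; no use of stain imagery beyond externally supplied polygons.
* Candidate estimation needs detectable marker structure; cell types
  defined purely by proportional shifts of shared genes seed poorly.
* The RL stage cannot create candidates, so cells missed by seeding
  remain merged into neighbours; at desk scale this is the dominant
  error source in label transfer.
* Single-device training; no checkpointing beyond the returned model.
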