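# txseg

Reference-guided transcript-to-cell segmentation for imaging-based spatial
transcriptomics, with whole-transcriptome expression imputation.

Imaging platforms (MERFISH, Xenium, CosMx, MERSCOPE) detect individual mRNA
molecules at subcellular resolution but do not tell you which cell each
molecule belongs to. `txseg` assigns molecules to cells so that the
resulting per-cell expression profiles agree with an scRNA-seq reference,
then lifts each segmented cell from the measured gene panel (hundreds of
genes) to a whole-transcriptome profile. It is aimed at computational
biologists who have a molecule table and a matched single-cell reference
and want segmentation that uses expression, not just geometry.

## Method

Segmentation is cast as reinforcement learning over per-molecule actions.
For molecule *i* with coordinates *(x_i, y_i)* and its *m* = 8 nearest
candidate cell centres, a policy network scores each pair through fused
embeddings — a trainable candidate embedding *f_j*, a gene embedding
*g_{gene(i)}*, and a location feature *h_{i,j}* computed from the offset to
the candidate centre — and a softmax yields assignment probabilities
C_prob. A separate binary head gives the noise probability N_prob,
initialised from the **noise distance score**

    NDS_i = max(0, 1 − d_i / Q_q(d)),

where *d_i* is the mean distance to the 100 nearest molecules and *Q_q* the
*q* = 0.999 quantile. Sampled actions *(G_i, H_i)* earn the multiplicative
reward NDS × CDS × ESS, where CDS scores proximity to the assigned cell's
centre (batch-quantile normalised) and ESS is feedback from a
**deconvolution model**: per cell type, trainable weights compress the
reference into adaptive expression states, a second trainable map predicts
each candidate's expected profile PE, and the per-gene residual between PE
and the observed profile E becomes the molecule-level ESS. The policy
minimises the REINFORCE loss

    −(1/n) Σ_i reward_i · [ln P(G_i) + ln P(H_i)],

alternating each epoch with 30 cosine-alignment steps of the deconvolution
model. After training, argmax assignment plus alpha-shape boundary
extraction, outside-polygon refinement and occurrence-weighted
nearest-reference averaging produce cell polygons, count matrices, and
imputed whole-transcriptome profiles. Candidate centres are either
estimated from marker-gene spatial density (score ln(A+1)·P per gene and
type, grid features, DBSCAN → K-means → MeanShift) or supplied externally,
e.g. as nuclear polygons, which also switch the location feature to
boundary distances and clip final polygons against foreign nuclei.

## Worked example

`examples/01_simulate_and_segment.py` simulates a 50-cell tissue with a
matched reference and segments it:

```
tissue: 5274 molecules from 50 cells (264 background)
candidates estimated: 51
molecules assigned:   4490 (85.1% of all molecules)
cells recovered:      49
final region loss:    0.0752
assignment precision: 0.950 (fraction of assigned molecules placed at their true cell)
```

51 candidate centres are estimated for 50 true cells; 85% of molecules are
assigned (the rest are called background — the tissue contains 5% true
background plus cell-periphery and misassigned stragglers pruned by
polygon refinement), and 95.0% of assigned molecules land on a candidate
at their true generating cell. The other examples show
imputation + label transfer, boundary/morphology evaluation, nuclear
priors, and the sequencing-spot adaptation. A thin CLI mirrors the same
stages (`txseg simulate | estimate-candidates | segment | impute |
evaluate`).

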