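# Methods

## Overview

`clonomark` implements a clonality-supervised approach to separating
malignant from bystander T cells in single-cell RNA-seq of cutaneous
T-cell lymphoma (mycosis fungoides) skin lesions. The method has three
stages, each usable on its own:

1. **TCR clonality partitioning** — reconstructed TCR chains label each
   cell as belonging to the patient's malignant clone or not, with no
   expression information involved.
2. **Adaptive logistic regression (NN-log-reg)** — an interpretable
   classifier predicts the clonality-derived malignancy label from
   expression alone, generalising to donors never seen in training.
3. **Adaptive-weight importance** — the classifier's per-cell attention
   weights are aggregated into per-gene importance scores and
   significant-gene lists.

A synthetic-data generator emulates the relevant structure of tumour-lesion
T-cell repertoires and expression so that the full method is testable at
desk scale without any data download.

## Clonality partitioning

Cells enter the analysis when they have at least one reconstructed TCR
chain and lack the CD8 phenotype (boolean metadata flag, or CD8A+CD8B
normalised expression above a configurable threshold, default 1.0). Each
donor is processed independently.

The dominant clonotype is the (α, β) chain pair carried by the largest
number of the donor's cells; a cell carrying several recombinants per
chain contributes every α×β pair it carries. Ties are broken by the larger
single-chain support (cells carrying the α plus cells carrying the β),
then lexicographically, so the result does not depend on cell order.

Labels are then assigned in order:

* **main clone** — the cell carries the dominant α or the dominant β;
* **related to main clone** — some chain of the cell is connected to the
  dominant pair in the chain co-occurrence graph (nodes: chain
  identifiers; edge: two identifiers observed in the same cell). By
  default the full connected component counts ("transitive"); a strict
  one-step variant is available (`transitive_association=False`);
* **bystander group** — among the remaining cells, groups of two or more
  sharing an identical (α-set, β-set) signature;
* **single bystander** — every remaining cell.

The published label definitions leave a gap for cells that share *some*
chain with another bystander without matching its full signature; we
assign these to the single-bystander class, which keeps the four labels a
partition on arbitrary input. On repertoires without such partial overlaps
(including everything the generator emits) the single-bystander class
coincides with the strict definition (no chain shared with any other
cell).

Main-clone and related cells form the malignant class (target 1), the two
bystander classes the benign class (target 0).

## The NN-log-reg classifier

For a cell's expression vector `x` (length G, non-negative normalised
values, TCR variable-segment genes removed):

    p(malignant | x) = sigmoid(bias_D + w_D * (a(x) . x))
    a(x) = softmax(sigmoid(bias_C + W_C tanh(bias_B + W_B tanh(bias_A + W_A x))))

The hypernetwork `a(x)` produces one weight per gene, per cell; the
softmax (over genes) makes the weight vector positive and sum to one, so
`a(x)` is a per-cell attention distribution and the model is a logistic
regression whose coefficients are set adaptively by the cell itself. The
hidden width H is 1000 at full scale and configurable (64 in the
desk-scale tests). Training minimises mean binary cross-entropy
(probabilities clamped at 1e-12) with full-batch Adam.

Because the softmax input is sigmoid-bounded to (0, 1), the attention
weights of any two genes can differ by at most a factor e ≈ 2.72. The
classifier's discriminative signal therefore comes from modest,
consistent re-weighting of informative genes around the per-cell weighted
mean, not from sparse attention.

### Numerical and optimisation choices

The published description fixes the architecture and the loss but not the
optimiser, initialisation, split proportions or stopping rule; those are
chosen here and exposed in `TrainConfig`:

* **Splits** — donors (never cells) are randomly assigned 0.6/0.2/0.2 to
  train/validation/test; the test set contains only unseen donors.
* **Initialisation** — uniform by layer fan-in; the first layer is
  additionally divided by the RMS of the training inputs so its tanh
  units start in the linear regime (raw normalised expression is far from
  unit scale, and a saturated first layer turns the hypernetwork into a
  cell-fingerprint memoriser with vanishing gradients toward real
  features). The attention output layer (`W_C`, `bias_C`) starts near
  zero so initial attention is uniform and every top-rank deviation that
  develops is learned rather than initialisation noise.
* **Head calibration** — `w_D` starts at 1.0 and `bias_D` at
  `logit(mean(y)) − w_D·mean(X)`, so initial predictions sit at the class
  prior. Without this, the attention-weighted input (nearly constant
  across cells) forces the optimiser to spend thousands of epochs
  calibrating the head while the attention parameters receive gradients
  scaled by an uninformative `w_D`.
* **Pathway-selective regularisation** — an L2 penalty (`hypernet_decay`)
  applies to the input-side matrices `W_A` and `W_B` only. At single-cell
  sample sizes the input-dependent pathway otherwise memorises each
  training cell's noise fingerprint, which both overfits and starves the
  per-gene attention parameters of gradient.
* **Model selection** — parameters are taken from the epoch with the best
  validation ROC AUC (`selection="auc"`, the default), not the best
  validation loss: the ranking quality that matters for donor-held-out
  prediction peaks long before the loss, which is dominated by
  calibration, stops improving. Loss-based selection is available
  (`selection="loss"`); early stopping triggers after `patience` epochs
  without improvement of the selection metric.

Training is deterministic given the seed: identical data, configuration
and seed reproduce bitwise-identical parameters.

### Baseline network

The standard feed-forward baseline uses five linear layers (1000, 1000,
1000, 32, 1 at full scale; widths configurable), SELU activations and a
final sigmoid, with the same loss, split, selection and evaluation
contracts. It provides no attention weights.

## Importance extraction

For every correctly classified cell (prediction thresholded at 0.5 equals
the target), the genes whose adaptive weight ranks in the top fraction
(default 0.5%, k = ceil(0.005·G), ties at the cutoff broken by gene
order) are that cell's important genes. Per gene, the percentage of
correctly classified cells whose top set contains it is reported;
genes reaching at least `min_cell_fraction` (default 50%) of cells form
the significant list of a dataset, and the train∩test intersection —
ordered by mean percentage — is the robust signature.

A structural property of the architecture worth knowing when reading
these lists: attention consistently *rewards* genes that are high in
malignant and low in bystander cells (attending them raises the weighted
sum for malignant cells and lowers it for bystander cells — useful in
both classes), and it symmetrically *suppresses* genes down-regulated in
malignant cells. Down-regulated markers therefore appear at the bottom,
not the top, of the attention ranking in a well-trained model, and
top-fraction importance recovers predominantly the up-regulated part of a
signature. At the full assay scale (G ≈ 44,800, k = 224) the slack in the
top set softens this; at desk scale (G = 2,000, k = 10) it is strict.

## The synthetic cohort generator

### Repertoires

Per donor: one dominant (α, β) pair seeds the main clone; most main-clone
cells carry exactly that pair, a few "bridge" cells pair one dominant
chain with a novel partner; related cells carry a bridge partner chain
plus a unique chain; bystander groups are duplicated two- or three-cell
signatures from fresh chains; single bystanders carry globally unique
chains (25% single-chain). Chain identifiers are drawn from real IMGT
TRAV/TRAJ/TRBV/TRBJ gene-name pools with random junctions, so the
recombinant parser is exercised end to end. The construction guarantees
the clonality stage re-derives the planted labels exactly, and validates
that the requested fractions keep the planted main clone dominant
(raising an error otherwise).

Label fractions default to 0.60/0.15/0.10/0.15
(main/related/group/single), cohort size to 5 donors × 100 cells.

### Expression

Counts are gamma-Poisson (negative binomial, dispersion θ = 10), zeroed
by Bernoulli dropout (p = 0.2), then scaled per cell to a fixed total
(10,000) as a stand-in for normalised RPKM values. Per-gene baseline
means follow Gamma(2, 2); the 10 informative genes (5 up, 5 down at
2-fold by default) have their baseline floored at 15 counts because the
real counterparts of such markers (MHC-I heavy chains, B2M, IL7R) sit in
the upper expression range, and a 2-fold shift on a weakly expressed gene
carries almost no information at single-cell noise levels. The noise
levels describe a high-sensitivity full-length platform (the study's
chemistry) rather than droplet-style sparsity. Twenty decoy genes named
after TCR V segments are included to exercise the exclusion step; they
carry no label-correlated shift, because per-cell normalisation would
otherwise leak a diffuse malignancy signal into every other gene through
the library-size denominator.

What the generator deliberately does not model: transcriptome-wide
co-expression modules, donor batch effects, cell-cycle or activation
programs, and the hundreds of genuinely differential genes a real
malignant clone carries. Passing tests on this generator show the method
recovers a *planted, localised* signal under count noise and dropout;
they do not certify performance on real lesions, where the signal is far
stronger but confounded.

## Problem sizes used in tests and the acceptance script

Desk-scale checks train on 5 donors × 100 cells, 2,000 genes (1,980 after
TCR exclusion), H = 64, at most 300 epochs (early stopping typically ends near
epoch 120) — a few seconds per fit on one CPU core. Clonality oracle checks use 200 random repertoires of
10–30 cells; round-trip checks 20 seeds of 2 × 60 cells; the null-effect
check trains 5 seeds at effect 0. The full-scale gene count (44,782)
appears only in shape/size checks.

## Known limitations

* The attention bound (factor e between any two genes) and the
  suppression of down-regulated markers are properties of the published
  architecture, reproduced faithfully here.
* With few donors, one donor constitutes the whole validation set, making
  model selection noisy; more donors stabilise it.
* Training hyperparameters were chosen by a small manual search on
  synthetic cohorts (the published description states a manual search
  without giving values); they are defaults, not tuned constants, and are
  all overridable.
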