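# clonomark

Identify malignant T cells in single-cell transcriptomes of cutaneous
T-cell lymphoma (mycosis fungoides) using the T-cell receptor as a natural
clonality label, and discover the genes that predict malignancy — without
ever showing the classifier a TCR gene.

Skin lesions in mycosis fungoides contain one dominant malignant T-cell
clone mixed with benign bystander T cells. Because every T cell carries a
practically unique TCR, the reconstructed α/β chains identify the clone
directly: the most frequent α+β combination in a patient's lesion marks
the malignant "main clone". `clonomark` turns that observation into a
supervised pipeline:

1. **Clonality partitioning** — per donor, cells are split into
   *main-clone*, *related-to-main-clone*, *bystander-group* and
   *single-bystander* classes from their chain-sharing structure; the
   first two are the malignant class (target 1), the last two benign
   (target 0).
2. **NN-log-reg** — an adaptive logistic regression over expression,

       p(malignant | x) = σ(bias_D + w_D · (a(x)ᵀ x)),
       a(x) = softmax(σ(bias_C + W_C tanh(bias_B + W_B tanh(bias_A + W_A x))))

   where the hypernetwork `a(x)` assigns each gene of each cell an
   attention weight (positive, summing to 1). All TRAV/TRAJ/TRBV/TRBJ
   genes are removed first, and evaluation is on donors never seen in
   training. A standard SELU feed-forward network is included as a
   baseline.
3. **Importance** — per correctly classified cell, the genes in the top
   0.5% of attention weights are "important"; genes important in ≥50% of
   cells in both the training and the held-out set form the robust
   malignancy signature.

A synthetic cohort generator (planted clonal repertoires + negative-
binomial/dropout expression with known informative genes) makes the whole
method testable end to end at desk scale. See `docs/methods.md` for the
model, its assumptions and the generator's scope.

## Worked example

Run the full synthetic pipeline — simulate a 5-donor × 100-cell cohort
(2,000 genes, 10 planted malignancy genes at 2-fold), re-derive clonality
labels from the TCR table, train the classifier with one donor held out,
and extract the gene signature:

```bash
clonomark run --seed 13 --out-dir demo
```

```
data: seconds=0.63
clonality: cells=500, main_clone=0.6000, related_to_main_clone=0.1500, bystander_group=0.1000, single_bystander=0.1500, seconds=0.01
train: genes=1980, epochs=122, auc_train=1.0000, auc_validation=0.9301, auc_test=0.9205, seconds=7.08
importance: overlap_genes=10, seconds=0.10
```

The clonality stage reproduces the planted class fractions exactly
(60/15/10/15%), and the classifier reaches ROC AUC 0.92 on the cells of a
donor it never saw. The signature (`demo/importance.tsv`) lists each gene
with the percentage of correctly classified cells for which it ranks in
the top 0.5% of attention weights:

```
gene      percent_train  percent_test  in_overlap
GENE0543  100.0          100.0         True
GENE0836  100.0          100.0         True
GENE1568  100.0          100.0         True
GENE1617  100.0          100.0         True
GENE1690  100.0          100.0         True
GENE0425   99.6           98.7         True
GENE1941   99.6           97.3         True
GENE0043   98.7           94.7         True
GENE1673   97.8           90.7         True
GENE0291   97.3           94.7         True
```

All five planted *up-regulated* genes of this cohort (GENE0043, GENE0291,
GENE0543, GENE0836, GENE1673) appear in the train∩test overlap at 90–100%
of cells. Down-regulated markers do not surface here: the attention
mechanism structurally favours genes high in malignant and low in
bystander cells and suppresses the mirror case (see `docs/methods.md`).

The library interface mirrors the CLI:

```python
from clonomark import (SimConfig, TrainConfig, simulate_dataset,
                       AdaptiveLogisticRegression)
from clonomark.data import drop_tcr_genes

cells, truth, dataset = simulate_dataset(SimConfig(seed=13))
results = AdaptiveLogisticRegression(drop_tcr_genes(dataset), hidden=64)\
    .fit(TrainConfig(seed=13))
print(results.summary())        # cells, epochs, per-split ROC AUC
results.plot_roc()              # matplotlib ROC curves
weights = results.adaptive_weights(dataset.matrix)  # per-cell attention
```

Subcommands `simulate`, `clonality`, `train`, `evaluate` and `importance`
run the stages separately on your own Matrix Market / TSV inputs
(`clonomark <cmd> --help`).

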