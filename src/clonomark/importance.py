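"""Per-gene importance from the adaptive weights of a fitted NN-log-reg.

For each correctly classified cell, the genes whose adaptive weight ranks in
the top 0.5% (by default) are that cell's "important" genes. Aggregating
over cells gives, per gene, the percentage of correctly classified cells in
which it is important; thresholding that percentage yields significant-gene
lists for the training and test sets, whose intersection is the robust
malignancy signature.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import LabeledDataset
from .model import FitResults

__all__ = [
    "ImportanceSummary",
    "correctly_classified",
    "top_fraction_genes",
    "gene_importance_summary",
    "significant_genes",
    "overlap_genes",
    "importance_from_results",
    "importance_table",
]


@dataclass
class ImportanceSummary:
    """Aggregated adaptive-weight importance for one evaluation set.

    ``per_gene_percent`` maps gene name -> percentage (0..100) of correctly
    classified cells for which the gene was in the top ``top_fraction`` of
    adaptive weights. ``per_cell_weights`` keeps the raw weight vectors of
    the correctly classified cells.
    """

    per_cell_weights: dict[str, np.ndarray]
    gene_names: list[str]
    top_fraction: float
    per_gene_percent: dict[str, float]
    set_tag: str = ""

    @property
    def n_cells(self) -> int:
        return len(self.per_cell_weights)


def correctly_classified(
    predictions: np.ndarray, targets: np.ndarray, cell_ids: list[str], threshold: float = 0.5
) -> list[str]:
    """Cells whose thresholded prediction equals the 0/1 target."""
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must lie in (0,1), got {threshold}")
    predictions = np.asarray(predictions, dtype=np.float64)
    targets = np.asarray(targets)
    calls = (predictions >= threshold).astype(int)
    return [cid for cid, c, y in zip(cell_ids, calls, targets) if c == y]


def top_fraction_genes(
    weights: np.ndarray, gene_names: list[str], fraction: float = 0.005
) -> set[str]:
    """The ``ceil(fraction * G)`` genes with the largest adaptive weights.

    Ties at the cutoff are broken by input gene order so the set size is
    exactly the ceiling count regardless of weight degeneracy.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0,1), got {fraction}")
    weights = np.asarray(weights, dtype=np.float64)
    g = weights.shape[0]
    k = math.ceil(fraction * g)
    # stable sort on (-weight, index): equal weights keep gene order
    order = np.lexsort((np.arange(g), -weights))
    return {gene_names[i] for i in order[:k]}


def gene_importance_summary(
    per_cell_top: dict[str, set[str]], gene_names: list[str]
) -> dict[str, float]:
    """Percentage of cells whose top set contains each gene."""
    n = len(per_cell_top)
    if n == 0:
        raise ValueError("no correctly classified cells: importance is undefined")
    counts = dict.fromkeys(gene_names, 0)
    for top in per_cell_top.values():
        for gene in top:
            counts[gene] += 1
    return {g: 100.0 * c / n for g, c in counts.items()}


def significant_genes(
    summary: ImportanceSummary, min_cell_fraction: float = 0.5
) -> list[str]:
    """Genes important in at least ``min_cell_fraction`` of cells,
    sorted by descending percentage (gene order breaking ties)."""
    if not 0.0 < min_cell_fraction <= 1.0:
        raise ValueError(f"min_cell_fraction must lie in (0,1], got {min_cell_fraction}")
    cut = 100.0 * min_cell_fraction
    order = {g: i for i, g in enumerate(summary.gene_names)}
    hits = [g for g, pct in summary.per_gene_percent.items() if pct >= cut]
    return sorted(hits, key=lambda g: (-summary.per_gene_percent[g], order[g]))


def overlap_genes(
    train_list: list[str],
    test_list: list[str],
    train_summary: ImportanceSummary | None = None,
    test_summary: ImportanceSummary | None = None,
) -> list[str]:
    """Intersection of two significant-gene lists, ordered by descending
    mean percentage across the two sets when summaries are supplied."""
    common = set(train_list) & set(test_list)
    if train_summary is not None and test_summary is not None:
        def mean_pct(g):
            return 0.5 * (
                train_summary.per_gene_percent.get(g, 0.0)
                + test_summary.per_gene_percent.get(g, 0.0)
            )
        return sorted(common, key=lambda g: (-mean_pct(g), g))
    order = {g: i for i, g in enumerate(train_list)}
    return sorted(common, key=lambda g: order[g])


def importance_from_results(
    results: FitResults,
    dataset: LabeledDataset,
    top_fraction: float = 0.005,
    threshold: float = 0.5,
    set_tag: str = "",
) -> ImportanceSummary:
    """Adaptive-weight importance of a fitted NN-log-reg on one dataset.

    Only correctly classified cells contribute; their adaptive weight
    vectors are ranked per cell and the top ``top_fraction`` genes tallied.
    """
    preds = results.predict(dataset.matrix)
    kept = set(correctly_classified(preds, dataset.targets, dataset.cell_ids, threshold))
    weights = results.adaptive_weights(dataset.matrix)
    per_cell_weights: dict[str, np.ndarray] = {}
    per_cell_top: dict[str, set[str]] = {}
    for i, cid in enumerate(dataset.cell_ids):
        if cid in kept:
            per_cell_weights[cid] = weights[i]
            per_cell_top[cid] = top_fraction_genes(weights[i], dataset.gene_names, top_fraction)
    per_gene = gene_importance_summary(per_cell_top, dataset.gene_names)
    return ImportanceSummary(
        per_cell_weights=per_cell_weights,
        gene_names=list(dataset.gene_names),
        top_fraction=top_fraction,
        per_gene_percent=per_gene,
        set_tag=set_tag,
    )


def importance_table(
    train_summary: ImportanceSummary,
    test_summary: ImportanceSummary,
    min_cell_fraction: float = 0.5,
) -> pd.DataFrame:
    """Tidy per-gene table: percent_train, percent_test, in_overlap."""
    train_sig = significant_genes(train_summary, min_cell_fraction)
    test_sig = significant_genes(test_summary, min_cell_fraction)
    overlap = set(overlap_genes(train_sig, test_sig, train_summary, test_summary))
    rows = [
        {
            "gene": g,
            "percent_train": train_summary.per_gene_percent.get(g, 0.0),
            "percent_test": test_summary.per_gene_percent.get(g, 0.0),
            "in_overlap": g in overlap,
        }
        for g in train_summary.gene_names
    ]
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["in_overlap", "percent_train", "percent_test"],
        ascending=[False, False, False],
        kind="stable",
    ).reset_index(drop=True)
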