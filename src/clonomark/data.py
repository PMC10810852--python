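"""Labeled expression datasets and donor-held-out splitting.

The in-memory container is a thin cells x genes matrix with aligned cell,
donor and target vectors. Values are non-negative normalised expression
(RPKM-like); no log transform is applied unless requested at training time.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = ["LabeledDataset", "TCR_GENE_PREFIXES", "exclude_tcr_genes", "split_by_donor"]

#: gene-name prefixes of the variable TCR segments; these genes carry the
#: clonality signal directly and are removed before any model sees the data.
TCR_GENE_PREFIXES = ("TRAV", "TRAJ", "TRBV", "TRBJ")


@dataclass
class LabeledDataset:
    """A cells x genes expression matrix with malignancy targets.

    Attributes
    ----------
    matrix : (n_cells, n_genes) ndarray
        Non-negative normalised expression values.
    gene_names : list of str
    cell_ids, donor_ids : list of str, length n_cells
    targets : (n_cells,) int ndarray of 0/1
        1 = clonal (malignant), 0 = bystander.
    """

    matrix: np.ndarray
    gene_names: list[str]
    cell_ids: list[str]
    donor_ids: list[str]
    targets: np.ndarray

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=np.float64)
        self.targets = np.asarray(self.targets, dtype=np.int64)
        n, g = self.matrix.shape
        if not (len(self.cell_ids) == len(self.donor_ids) == len(self.targets) == n):
            raise ValueError(
                f"row mismatch: matrix has {n} cells but "
                f"{len(self.cell_ids)} ids / {len(self.donor_ids)} donors / "
                f"{len(self.targets)} targets"
            )
        if len(self.gene_names) != g:
            raise ValueError(
                f"column mismatch: matrix has {g} genes but {len(self.gene_names)} names"
            )
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("expression matrix contains non-finite values")
        if np.any(self.matrix < 0):
            raise ValueError("expression matrix contains negative values")

    @property
    def n_cells(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_genes(self) -> int:
        return self.matrix.shape[1]

    @property
    def donors(self) -> list[str]:
        """Unique donor ids in first-appearance order."""
        seen: dict[str, None] = {}
        for d in self.donor_ids:
            seen.setdefault(d)
        return list(seen)

    def subset(self, mask: np.ndarray) -> "LabeledDataset":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return LabeledDataset(
            matrix=self.matrix[idx],
            gene_names=list(self.gene_names),
            cell_ids=[self.cell_ids[i] for i in idx],
            donor_ids=[self.donor_ids[i] for i in idx],
            targets=self.targets[idx],
        )

    def subset_donors(self, donors) -> "LabeledDataset":
        wanted = set(donors)
        mask = np.array([d in wanted for d in self.donor_ids])
        return self.subset(mask)


def exclude_tcr_genes(
    matrix: np.ndarray, gene_names: list[str]
) -> tuple[np.ndarray, list[str]]:
    """Drop genes named after the variable TCR segments.

    Removes every gene whose name begins (case-insensitively) with TRAV,
    TRAJ, TRBV or TRBJ; other columns keep their order.
    """
    keep = [
        i
        for i, name in enumerate(gene_names)
        if not name.upper().startswith(TCR_GENE_PREFIXES)
    ]
    return np.asarray(matrix)[:, keep], [gene_names[i] for i in keep]


def drop_tcr_genes(dataset: LabeledDataset) -> LabeledDataset:
    """:func:`exclude_tcr_genes` applied to a :class:`LabeledDataset`."""
    matrix, names = exclude_tcr_genes(dataset.matrix, dataset.gene_names)
    return replace(dataset, matrix=matrix, gene_names=names)


def split_by_donor(
    dataset: LabeledDataset,
    fractions: tuple[float, float, float] = (0.6, 0.2, 0.2),
    seed: int = 0,
) -> tuple[LabeledDataset, LabeledDataset, LabeledDataset]:
    """Partition a dataset into train/validation/test sets by donor.

    Donors — not cells — are randomly assigned, so the test set consists
    exclusively of cells from donors unseen during training. Each split
    receives at least one donor; validation and test donor counts are the
    rounded fractions of the donor total.

    Raises
    ------
    ValueError
        If fewer than 3 donors are present or the fractions are invalid.
    """
    if len(fractions) != 3 or any(f <= 0 for f in fractions):
        raise ValueError(f"fractions must be 3 positive numbers, got {fractions}")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError(f"fractions must sum to 1, got {fractions}")
    donors = sorted(set(dataset.donor_ids))
    n = len(donors)
    if n < 3:
        raise ValueError(f"need at least 3 donors for a donor-held-out split, got {n}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_val = max(1, round(fractions[1] * n))
    n_test = max(1, round(fractions[2] * n))
    if n_val + n_test >= n:
        n_val = n_test = 1
    test_donors = [donors[i] for i in order[:n_test]]
    val_donors = [donors[i] for i in order[n_test : n_test + n_val]]
    train_donors = [donors[i] for i in order[n_test + n_val :]]
    return (
        dataset.subset_donors(train_donors),
        dataset.subset_donors(val_donors),
        dataset.subset_donors(test_donors),
    )
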