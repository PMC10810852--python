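"""TCR-based clonality partitioning of a donor's T cells.

Each donor's admitted cells (at least one reconstructed chain, CD8-negative)
are partitioned into four groups:

* ``MAIN_CLONE`` — cells carrying the dominant alpha or the dominant beta
  chain, where the dominant (alpha, beta) pair is the combination shared by
  the largest number of the donor's cells;
* ``RELATED_TO_MAIN_CLONE`` — cells with no dominant chain but with a chain
  connected to the dominant pair through the chain co-occurrence graph
  (two identifiers are linked when some cell carries both);
* ``BYSTANDER_GROUP`` — remaining cells forming groups of two or more with an
  identical (alpha-set, beta-set) signature;
* ``SINGLE_BYSTANDER`` — all remaining cells.

Main-clone and related cells are the malignant clone (target 1); bystander
groups and single bystanders are benign (target 0). Donors are processed
independently: clonality never crosses donors.
"""

from __future__ import annotations

import enum
from collections import Counter, defaultdict
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

from .tcr import CellRecord

__all__ = [
    "ClonalityLabel",
    "ClonalityAssignment",
    "CD8Rule",
    "NoDominantPairError",
    "admit_cells",
    "dominant_pair",
    "assign_clonality",
    "clonality_fractions",
]


class ClonalityLabel(enum.Enum):
    MAIN_CLONE = "main_clone"
    RELATED_TO_MAIN_CLONE = "related_to_main_clone"
    BYSTANDER_GROUP = "bystander_group"
    SINGLE_BYSTANDER = "single_bystander"
    EXCLUDED = "excluded"


#: labels counted as the malignant clone
CLONAL_LABELS = frozenset({ClonalityLabel.MAIN_CLONE, ClonalityLabel.RELATED_TO_MAIN_CLONE})
BYSTANDER_LABELS = frozenset({ClonalityLabel.BYSTANDER_GROUP, ClonalityLabel.SINGLE_BYSTANDER})


@dataclass(frozen=True)
class ClonalityAssignment:
    cell_id: str
    donor_id: str
    label: ClonalityLabel
    malignancy_target: int | None
    dominant_alpha: str | None = None
    dominant_beta: str | None = None


@dataclass(frozen=True)
class CD8Rule:
    """How CD8-positive cells are recognised for exclusion.

    Either trust the per-cell boolean flag (``use_flag=True``) or, when the
    caller derives the flag from expression, a cell is CD8-positive when its
    CD8A+CD8B normalised expression exceeds ``expression_threshold``.
    The thresholding itself happens where expression is available (see
    :func:`clonomark.io.cd8_flag_from_expression`); this rule object carries
    the configuration.
    """

    use_flag: bool = True
    expression_threshold: float = 1.0


class NoDominantPairError(ValueError):
    """Raised when no cell of a donor carries both an alpha and a beta chain."""


def admit_cells(cells: Sequence[CellRecord], cd8_rule: CD8Rule | None = None) -> list[CellRecord]:
    """Select cells eligible for clonality/ML analysis.

    Keeps cells with at least one reconstructed chain and without the CD8
    phenotype. Order is preserved; the input list is untouched.
    """
    del cd8_rule  # the flag is already materialised on the records
    return [c for c in cells if c.has_chain and not c.cd8_positive]


def _pair_counts(cells: Iterable[CellRecord]) -> Counter:
    counts: Counter = Counter()
    for cell in cells:
        for a in cell.alpha_set:
            for b in cell.beta_set:
                counts[(a, b)] += 1
    return counts


def dominant_pair(cells: Sequence[CellRecord], donor_id: str | None = None) -> tuple[str, str]:
    """The (alpha, beta) identifier pair carried by the most cells of a donor.

    A cell carrying multiple recombinants contributes every alpha x beta pair
    it carries, once each. Ties are broken by the larger total single-chain
    support (number of cells carrying the alpha plus number carrying the
    beta), then by lexicographic order of the pair, so the result is
    deterministic and independent of cell order.
    """
    if donor_id is not None:
        cells = [c for c in cells if c.donor_id == donor_id]
    counts = _pair_counts(cells)
    if not counts:
        raise NoDominantPairError(
            "no cell carries both an alpha and a beta chain"
            + (f" for donor {donor_id!r}" if donor_id is not None else "")
        )
    alpha_support: Counter = Counter()
    beta_support: Counter = Counter()
    for cell in cells:
        for a in cell.alpha_set:
            alpha_support[a] += 1
        for b in cell.beta_set:
            beta_support[b] += 1

    def sort_key(pair: tuple[str, str]):
        a, b = pair
        return (-counts[pair], -(alpha_support[a] + beta_support[b]), a, b)

    return min(counts, key=sort_key)


def _dominant_component(cells: Sequence[CellRecord], seeds: Iterable[str]) -> set[str]:
    """Connected component of the chain co-occurrence graph containing ``seeds``."""
    adjacency: defaultdict[str, set[str]] = defaultdict(set)
    for cell in cells:
        chains = cell.chains
        for ch in chains:
            adjacency[ch].update(chains - {ch})
    component = set(seeds)
    frontier = set(seeds)
    while frontier:
        nxt: set[str] = set()
        for ch in frontier:
            nxt.update(adjacency.get(ch, ()))
        frontier = nxt - component
        component |= frontier
    return component


def assign_clonality(
    cells: Sequence[CellRecord],
    *,
    transitive_association: bool = True,
) -> list[ClonalityAssignment]:
    """Partition admitted cells into the four clonality groups, per donor.

    Parameters
    ----------
    cells : sequence of CellRecord
        Already admitted cells (chains present, CD8-negative); any donors
        may be mixed, each is processed independently.
    transitive_association : bool
        If True (default), "related to main clone" reaches through the full
        connected component of the dominant chains in the co-occurrence
        graph; if False, only chains one edge away from the dominant pair
        qualify.

    Returns
    -------
    list of ClonalityAssignment, one per input cell, in input order.
    """
    by_donor: defaultdict[str, list[int]] = defaultdict(list)
    for i, cell in enumerate(cells):
        by_donor[cell.donor_id].append(i)

    out: list[ClonalityAssignment | None] = [None] * len(cells)
    for donor_id in sorted(by_donor):
        idx = by_donor[donor_id]
        donor_cells = [cells[i] for i in idx]
        try:
            a1, b1 = dominant_pair(donor_cells)
        except NoDominantPairError:
            a1 = b1 = None

        labels = _label_donor(donor_cells, a1, b1, transitive_association)
        for i, label in zip(idx, labels):
            target = 1 if label in CLONAL_LABELS else 0
            out[i] = ClonalityAssignment(
                cell_id=cells[i].cell_id,
                donor_id=donor_id,
                label=label,
                malignancy_target=target,
                dominant_alpha=a1,
                dominant_beta=b1,
            )
    return out  # type: ignore[return-value]


def _label_donor(
    donor_cells: Sequence[CellRecord],
    a1: str | None,
    b1: str | None,
    transitive: bool,
) -> list[ClonalityLabel]:
    n = len(donor_cells)
    labels: list[ClonalityLabel | None] = [None] * n

    if a1 is not None:
        # (2) main clone: carries the dominant alpha or the dominant beta
        for i, cell in enumerate(donor_cells):
            if a1 in cell.alpha_set or b1 in cell.beta_set:
                labels[i] = ClonalityLabel.MAIN_CLONE
        # (3) related: some chain associated with the dominant pair
        if transitive:
            component = _dominant_component(donor_cells, (a1, b1))
        else:
            component = {a1, b1}
            for cell in donor_cells:
                chains = cell.chains
                if a1 in chains or b1 in chains:
                    component |= chains
        for i, cell in enumerate(donor_cells):
            if labels[i] is None and cell.chains & component:
                labels[i] = ClonalityLabel.RELATED_TO_MAIN_CLONE

    # (4) bystander groups: >=2 remaining cells with identical chain signature
    signature_members: defaultdict[tuple, list[int]] = defaultdict(list)
    for i, cell in enumerate(donor_cells):
        if labels[i] is None:
            sig = (tuple(sorted(cell.alpha_set)), tuple(sorted(cell.beta_set)))
            signature_members[sig].append(i)
    for members in signature_members.values():
        label = (
            ClonalityLabel.BYSTANDER_GROUP
            if len(members) >= 2
            else ClonalityLabel.SINGLE_BYSTANDER  # (5) everything left
        )
        for i in members:
            labels[i] = label
    return labels  # type: ignore[return-value]


def clonality_fractions(
    assignments: Sequence[ClonalityAssignment],
) -> Mapping[ClonalityLabel, float]:
    """Fraction of non-excluded cells in each of the four clonality groups."""
    kept = [a for a in assignments if a.label is not ClonalityLabel.EXCLUDED]
    if not kept:
        raise ValueError("no non-excluded assignments to summarise")
    n = len(kept)
    counts = Counter(a.label for a in kept)
    return {
        label: counts.get(label, 0) / n
        for label in (
            ClonalityLabel.MAIN_CLONE,
            ClonalityLabel.RELATED_TO_MAIN_CLONE,
            ClonalityLabel.BYSTANDER_GROUP,
            ClonalityLabel.SINGLE_BYSTANDER,
        )
    }
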