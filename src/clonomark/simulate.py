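"""Synthetic TCR repertoires and expression matrices with known ground truth.

The repertoire generator plants, per donor, the structure seen in tumour
skin lesions: one dominant alpha+beta clonotype (the malignant main clone,
some of whose cells pair a dominant chain with a novel partner), cells
related to it through shared chains, small duplicated-signature bystander
groups, and single bystanders with unique chains. Healthy-like TCR
diversity appears as the bystanders' unique chain draws.

The expression generator emulates normalised single-cell transcript counts:
negative-binomial baseline per gene, Bernoulli dropout, per-cell scaling to
a fixed total, and a minority of informative genes whose mean is shifted by
a signed log2 effect in malignant cells only (half up, half down, echoing
MHC-I-like up- and IL7R-like down-regulation). Decoy genes named after TCR
V segments are included so that TCR-gene exclusion is exercised end to end;
by default they carry no label-correlated shift (a shift would leak a
diffuse malignancy signal into every other gene through the per-cell
normalisation denominator).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .clonality import ClonalityLabel
from .data import LabeledDataset
from .tcr import CellRecord, Chain, Tissue

__all__ = ["SimConfig", "GroundTruth", "simulate_repertoire", "simulate_expression", "simulate_dataset"]

TRAV_POOL = [
    "TRAV1-1", "TRAV1-2", "TRAV2", "TRAV3", "TRAV4", "TRAV5", "TRAV6",
    "TRAV8-1", "TRAV8-2", "TRAV8-4", "TRAV9-2", "TRAV10", "TRAV12-1",
    "TRAV12-2", "TRAV13-1", "TRAV14DV4", "TRAV17", "TRAV19", "TRAV21",
    "TRAV26-1", "TRAV27", "TRAV29DV5", "TRAV35", "TRAV38-1", "TRAV41",
]
TRAJ_POOL = [
    "TRAJ4", "TRAJ6", "TRAJ9", "TRAJ12", "TRAJ15", "TRAJ20", "TRAJ23",
    "TRAJ27", "TRAJ30", "TRAJ33", "TRAJ37", "TRAJ40", "TRAJ42", "TRAJ45",
    "TRAJ49", "TRAJ52", "TRAJ54", "TRAJ57",
]
TRBV_POOL = [
    "TRBV2", "TRBV3-1", "TRBV4-1", "TRBV5-1", "TRBV5-4", "TRBV6-1",
    "TRBV6-5", "TRBV7-2", "TRBV7-9", "TRBV9", "TRBV10-3", "TRBV11-2",
    "TRBV12-3", "TRBV13", "TRBV14", "TRBV15", "TRBV18", "TRBV19",
    "TRBV20-1", "TRBV24-1", "TRBV25-1", "TRBV27", "TRBV28", "TRBV29-1",
    "TRBV30",
]
TRBJ_POOL = [
    "TRBJ1-1", "TRBJ1-2", "TRBJ1-3", "TRBJ1-4", "TRBJ1-5", "TRBJ1-6",
    "TRBJ2-1", "TRBJ2-2", "TRBJ2-3", "TRBJ2-4", "TRBJ2-5", "TRBJ2-6",
    "TRBJ2-7",
]


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults describe a desk-scale tumour-lesion cohort: 5 donors of 100
    cells, clonality fractions (0.60, 0.15, 0.10, 0.15), 2,000 genes of
    which 10 are malignancy-informative at a 2-fold effect (half up, half
    down), negative-binomial noise with dispersion 10 and 20% dropout.
    """

    n_donors: int = 5
    cells_per_donor: int = 100
    fractions: tuple[float, float, float, float] = (0.60, 0.15, 0.10, 0.15)
    n_genes: int = 2000
    n_informative: int = 10
    log2_effect: float = 1.0
    nb_mean_shape: float = 2.0
    nb_mean_scale: float = 2.0
    nb_dispersion: float = 10.0
    dropout: float = 0.2
    n_tcr_decoys: int = 20
    tcr_decoy_log2_effect: float = 0.0
    informative_min_mean: float = 15.0
    target_sum: float = 1e4
    chain_pool_size: int = 0  # 0 = use the full built-in name pools
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.fractions) != 4 or any(f < 0 for f in self.fractions):
            raise ValueError(f"need 4 non-negative label fractions, got {self.fractions}")
        if abs(sum(self.fractions) - 1.0) > 1e-9:
            raise ValueError(f"label fractions must sum to 1, got {self.fractions}")
        if self.n_donors < 1 or self.cells_per_donor < 1 or self.n_genes < 1:
            raise ValueError("n_donors, cells_per_donor and n_genes must be positive")
        if self.n_informative > self.n_genes - self.n_tcr_decoys:
            raise ValueError(
                f"n_informative={self.n_informative} exceeds available non-TCR genes "
                f"({self.n_genes - self.n_tcr_decoys})"
            )
        if not 0.0 <= self.dropout < 1.0:
            raise ValueError(f"dropout must be in [0,1), got {self.dropout}")


@dataclass
class GroundTruth:
    """Planted labels and effects accompanying a simulated cohort."""

    labels: dict[str, ClonalityLabel]
    targets: dict[str, int]
    dominant_pairs: dict[str, tuple[str, str] | None]
    informative_genes: dict[str, float] = field(default_factory=dict)
    gene_names: list[str] = field(default_factory=list)


_DNA = np.array(list("ACGT"))


def _label_counts(n: int, fractions) -> dict[ClonalityLabel, int]:
    """Largest-remainder apportionment of n cells to the four labels."""
    labels = [
        ClonalityLabel.MAIN_CLONE,
        ClonalityLabel.RELATED_TO_MAIN_CLONE,
        ClonalityLabel.BYSTANDER_GROUP,
        ClonalityLabel.SINGLE_BYSTANDER,
    ]
    raw = [f * n for f in fractions]
    counts = [int(np.floor(r)) for r in raw]
    remainder = n - sum(counts)
    order = sorted(range(4), key=lambda i: raw[i] - counts[i], reverse=True)
    for i in order[:remainder]:
        counts[i] += 1
    return dict(zip(labels, counts))


class _ChainFactory:
    """Draws recombinant identifiers, never repeating one."""

    def __init__(self, rng: np.random.Generator, pool_size: int = 0):
        self.rng = rng
        k = pool_size or None
        self.pools = {
            Chain.ALPHA: (TRAV_POOL[:k], TRAJ_POOL[:k]),
            Chain.BETA: (TRBV_POOL[:k], TRBJ_POOL[:k]),
        }
        self.used: set[str] = set()

    def new(self, chain: Chain) -> str:
        v_pool, j_pool = self.pools[chain]
        while True:
            v = v_pool[int(self.rng.integers(len(v_pool)))]
            j = j_pool[int(self.rng.integers(len(j_pool)))]
            length = 3 * int(self.rng.integers(7, 14))
            junction = "".join(self.rng.choice(_DNA, size=length))
            ident = f"{v}_{junction}_{j}"
            if ident not in self.used:
                self.used.add(ident)
                return ident


def _group_sizes(n: int) -> list[int]:
    """Split n bystander-group cells into groups of >=2 (pairs, last may be 3)."""
    if n == 0:
        return []
    if n == 1:
        raise ValueError("a single bystander-group cell is infeasible (groups need >=2)")
    sizes = [2] * (n // 2)
    if n % 2:
        sizes[-1] = 3
    return sizes


def simulate_repertoire(config: SimConfig) -> tuple[list[CellRecord], GroundTruth]:
    """Generate CD4-like, chain-bearing cells with planted clonality labels.

    The construction guarantees that :func:`clonomark.clonality.assign_clonality`
    recovers the planted labels exactly: the dominant pair's exact-match count
    strictly exceeds every other alpha x beta pair count, related cells reach
    the main clone through exactly one shared bridge chain, bystander groups
    duplicate a signature unique to the group, and single bystanders carry
    chains found in no other cell of the donor.
    """
    rng = np.random.default_rng(config.seed)
    factory = _ChainFactory(rng, config.chain_pool_size)
    cells: list[CellRecord] = []
    labels: dict[str, ClonalityLabel] = {}
    dominant: dict[str, tuple[str, str] | None] = {}
    counter = itertools.count()

    for d in range(config.n_donors):
        donor = f"donor{d + 1:02d}"
        counts = _label_counts(config.cells_per_donor, config.fractions)
        n_mc = counts[ClonalityLabel.MAIN_CLONE]
        n_rel = counts[ClonalityLabel.RELATED_TO_MAIN_CLONE]
        n_bg = counts[ClonalityLabel.BYSTANDER_GROUP]
        n_sb = counts[ClonalityLabel.SINGLE_BYSTANDER]
        sizes = _group_sizes(n_bg)
        max_group = max(sizes, default=0)

        donor_cells: list[tuple[frozenset, frozenset, ClonalityLabel]] = []
        if n_mc > 0:
            a1 = factory.new(Chain.ALPHA)
            b1 = factory.new(Chain.BETA)
            dominant[donor] = (a1, b1)
            # bridge cells pair a novel chain with a dominant one; they stay
            # MAIN_CLONE but open a path for RELATED cells
            budget = n_mc - max(2 if (n_rel or n_bg or n_sb) else 1, max_group + 1)
            n_bridges = min(n_rel, max(budget, 0))
            if n_rel > 0 and n_bridges < 1:
                raise ValueError(
                    f"infeasible fractions for donor size {config.cells_per_donor}: "
                    "related cells requested but the main clone is too small to "
                    "stay dominant alongside a bridge cell"
                )
            n_exact = n_mc - n_bridges
            others = n_rel + n_bg + n_sb
            if others and (n_exact < 2 or n_exact <= max_group):
                raise ValueError(
                    f"infeasible fractions {config.fractions} at donor size "
                    f"{config.cells_per_donor}: the planted main clone "
                    f"({n_exact} exact cells) would not stay dominant over "
                    f"bystander groups of up to {max_group} cells"
                )
            bridges: list[tuple[Chain, str]] = []
            for k in range(n_bridges):
                if k % 2 == 0:
                    a_new = factory.new(Chain.ALPHA)
                    donor_cells.append((frozenset({a_new}), frozenset({b1}),
                                        ClonalityLabel.MAIN_CLONE))
                    bridges.append((Chain.ALPHA, a_new))
                else:
                    b_new = factory.new(Chain.BETA)
                    donor_cells.append((frozenset({a1}), frozenset({b_new}),
                                        ClonalityLabel.MAIN_CLONE))
                    bridges.append((Chain.BETA, b_new))
            for _ in range(n_mc - n_bridges):
                donor_cells.append((frozenset({a1}), frozenset({b1}),
                                    ClonalityLabel.MAIN_CLONE))
            for k in range(n_rel):
                chain, ident = bridges[k % len(bridges)]
                if chain is Chain.ALPHA:  # bridge alpha + novel beta partner
                    sig = (frozenset({ident}), frozenset({factory.new(Chain.BETA)}))
                else:
                    sig = (frozenset({factory.new(Chain.ALPHA)}), frozenset({ident}))
                donor_cells.append((*sig, ClonalityLabel.RELATED_TO_MAIN_CLONE))
        else:
            dominant[donor] = None
            if n_rel > 0:
                raise ValueError("related cells requested without a main clone")

        # bystander groups: duplicated signatures from fresh chains; when no
        # main clone exists cells are single-chain so no alpha x beta pair
        # can usurp dominance
        paired_ok = n_mc > 0
        for size in sizes:
            if paired_ok:
                sig = (frozenset({factory.new(Chain.ALPHA)}),
                       frozenset({factory.new(Chain.BETA)}))
            else:
                sig = (frozenset({factory.new(Chain.ALPHA)}), frozenset())
            for _ in range(size):
                donor_cells.append((*sig, ClonalityLabel.BYSTANDER_GROUP))

        for _ in range(n_sb):
            if paired_ok and rng.random() < 0.75:
                sig = (frozenset({factory.new(Chain.ALPHA)}),
                       frozenset({factory.new(Chain.BETA)}))
            elif rng.random() < 0.5:
                sig = (frozenset({factory.new(Chain.ALPHA)}), frozenset())
            else:
                sig = (frozenset(), frozenset({factory.new(Chain.BETA)}))
            donor_cells.append((*sig, ClonalityLabel.SINGLE_BYSTANDER))

        order = rng.permutation(len(donor_cells))
        for i in order:
            alpha, beta, label = donor_cells[i]
            cid = f"cell{next(counter):05d}"
            cells.append(CellRecord(cell_id=cid, donor_id=donor, tissue=Tissue.SKIN,
                                    alpha_set=alpha, beta_set=beta, cd8_positive=False))
            labels[cid] = label

    targets = {
        cid: int(lab in (ClonalityLabel.MAIN_CLONE, ClonalityLabel.RELATED_TO_MAIN_CLONE))
        for cid, lab in labels.items()
    }
    return cells, GroundTruth(labels=labels, targets=targets, dominant_pairs=dominant)


def simulate_expression(
    cells: list[CellRecord], truth: GroundTruth, config: SimConfig
) -> LabeledDataset:
    """Expression matrix for a simulated repertoire.

    Counts are gamma-Poisson (negative binomial with dispersion
    ``nb_dispersion``), zeroed by Bernoulli dropout, then each cell is
    scaled to ``target_sum`` total — a stand-in for normalised RPKM values.
    Informative genes are mean-shifted by ``2**log2_effect`` in malignant
    cells only; decoy TCR-named genes are up-shifted in malignant cells and
    must be removed by TCR-gene exclusion before modelling.
    """
    rng = np.random.default_rng(config.seed + 1)
    n_cells = len(cells)
    g = config.n_genes
    n_decoy = config.n_tcr_decoys

    decoy_pool = [n for n in TRBV_POOL + TRAV_POOL]
    gene_names = [decoy_pool[i % len(decoy_pool)] + ("" if i < len(decoy_pool) else f".{i // len(decoy_pool)}")
                  for i in range(n_decoy)]
    gene_names += [f"GENE{i:04d}" for i in range(g - n_decoy)]

    base_mean = rng.gamma(shape=config.nb_mean_shape, scale=config.nb_mean_scale, size=g)
    informative_idx = rng.choice(np.arange(n_decoy, g), size=config.n_informative, replace=False)
    # malignancy markers are moderately expressed; floor their baseline mean
    base_mean[informative_idx] = np.maximum(base_mean[informative_idx],
                                            config.informative_min_mean) + config.nb_mean_scale
    effects = np.zeros(g)
    half = config.n_informative // 2
    effects[informative_idx[:config.n_informative - half]] = config.log2_effect
    effects[informative_idx[config.n_informative - half:]] = -config.log2_effect
    if n_decoy:
        effects[:n_decoy] = config.tcr_decoy_log2_effect

    y = np.array([truth.targets[c.cell_id] for c in cells], dtype=np.int64)
    mean = np.tile(base_mean, (n_cells, 1))
    mean[y == 1] = mean[y == 1] * (2.0 ** effects)

    theta = config.nb_dispersion
    lam = rng.gamma(shape=theta, scale=mean / theta)
    counts = rng.poisson(lam).astype(np.float64)
    if config.dropout > 0:
        keep = rng.random(size=counts.shape) >= config.dropout
        counts *= keep
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    matrix = counts / totals * config.target_sum

    truth.informative_genes = {
        gene_names[i]: float(effects[i]) for i in sorted(informative_idx)
    }
    truth.gene_names = gene_names
    return LabeledDataset(
        matrix=matrix,
        gene_names=gene_names,
        cell_ids=[c.cell_id for c in cells],
        donor_ids=[c.donor_id for c in cells],
        targets=y,
    )


def simulate_dataset(config: SimConfig) -> tuple[list[CellRecord], GroundTruth, LabeledDataset]:
    """Repertoire plus matched expression in one call."""
    cells, truth = simulate_repertoire(config)
    dataset = simulate_expression(cells, truth, config)
    return cells, truth, dataset
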