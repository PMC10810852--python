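"""T-cell receptor recombinant identifiers and per-cell TCR records.

A reconstructed TCR chain is identified by the underscore-joined template
``<V locus>_<junction sequence>_<J locus>``, e.g. ``TRBV20-1_TGTAGC_TRBJ2-7``.
V and J locus names never contain underscores, so the junction is everything
between the first and the last underscore-delimited gene name.
"""

from __future__ import annotations

import enum
import re
from dataclasses import dataclass, field

__all__ = [
    "Chain",
    "Tissue",
    "TcrRecombinant",
    "CellRecord",
    "parse_recombinant",
    "RecombinantParseError",
]

_JUNCTION_RE = re.compile(r"^[ACGTN]+$")


class Chain(enum.Enum):
    ALPHA = "A"
    BETA = "B"


class Tissue(enum.Enum):
    SKIN = "SKIN"
    BLOOD = "BLOOD"
    OTHER = "OTHER"


class RecombinantParseError(ValueError):
    """Raised when a recombinant identifier does not follow the template."""


@dataclass(frozen=True)
class TcrRecombinant:
    """One reconstructed alpha or beta chain.

    Attributes
    ----------
    chain : Chain
        ALPHA or BETA, inferred from the TRAV/TRAJ vs TRBV/TRBJ locus prefixes.
    v_locus, j_locus : str
        IMGT-style gene names.
    junction : str
        Nucleotide junction sequence between the V and J loci.
    """

    chain: Chain
    v_locus: str
    junction: str
    j_locus: str

    @property
    def identifier(self) -> str:
        return f"{self.v_locus}_{self.junction}_{self.j_locus}"

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.identifier


def _infer_chain(v_locus: str, j_locus: str, identifier: str) -> Chain:
    v = v_locus.upper()
    j = j_locus.upper()
    if v.startswith("TRAV") or j.startswith("TRAJ"):
        if v.startswith("TRBV") or j.startswith("TRBJ"):
            raise RecombinantParseError(
                f"mixed alpha/beta loci in recombinant {identifier!r}"
            )
        return Chain.ALPHA
    if v.startswith("TRBV") or j.startswith("TRBJ"):
        return Chain.BETA
    raise RecombinantParseError(
        f"cannot infer chain from loci {v_locus!r}/{j_locus!r} in {identifier!r}"
    )


def parse_recombinant(identifier: str, chain: Chain | None = None) -> TcrRecombinant:
    """Parse an underscore-template recombinant identifier.

    The junction is the middle segment between the first and last underscore:
    gene names contain no underscore, but the parser tolerates junctions that
    (pathologically) would — the first and last segments are the loci.

    Parameters
    ----------
    identifier : str
        String of the form ``<V locus>_<junction>_<J locus>``.
    chain : Chain, optional
        Override chain inference from the locus-name prefixes.

    Raises
    ------
    RecombinantParseError
        If the identifier has fewer than three segments, an empty segment,
        or a junction containing characters outside ``{A,C,G,T,N}``.
    """
    parts = identifier.split("_")
    if len(parts) < 3:
        raise RecombinantParseError(
            f"malformed recombinant identifier {identifier!r}: "
            f"expected '<V>_<junction>_<J>', got {len(parts)} segment(s)"
        )
    v_locus, j_locus = parts[0], parts[-1]
    junction = "_".join(parts[1:-1])
    for name, seg in (("V locus", v_locus), ("junction", junction), ("J locus", j_locus)):
        if not seg:
            raise RecombinantParseError(
                f"malformed recombinant identifier {identifier!r}: empty {name}"
            )
    if not _JUNCTION_RE.match(junction.upper()):
        raise RecombinantParseError(
            f"junction {junction!r} in {identifier!r} is not a DNA sequence "
            "over {A,C,G,T,N}"
        )
    if chain is None:
        chain = _infer_chain(v_locus, j_locus, identifier)
    return TcrRecombinant(chain=chain, v_locus=v_locus, junction=junction, j_locus=j_locus)


@dataclass
class CellRecord:
    """A single T cell's identity and reconstructed TCR chain sets.

    ``alpha_set`` and ``beta_set`` hold recombinant *identifiers* (strings);
    either may be empty, and a cell may carry several recombinants per chain
    (the reconstruction emits a set of sequences per cell).
    """

    cell_id: str
    donor_id: str
    tissue: Tissue = Tissue.SKIN
    alpha_set: frozenset[str] = field(default_factory=frozenset)
    beta_set: frozenset[str] = field(default_factory=frozenset)
    cd8_positive: bool = False

    def __post_init__(self) -> None:
        self.alpha_set = frozenset(self.alpha_set)
        self.beta_set = frozenset(self.beta_set)

    @property
    def has_chain(self) -> bool:
        return bool(self.alpha_set or self.beta_set)

    @property
    def chains(self) -> frozenset[str]:
        return self.alpha_set | self.beta_set
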