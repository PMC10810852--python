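"""Readers, writers and configuration shared by the pipeline stages.

File formats are deliberately plain: Matrix Market (with gene/cell name
sidecars) or dense TSV for expression, tab-separated tables for TCR
recombinants, metadata, labels and importance, and ``key = value`` text for
configuration. All writes are atomic (temp file + rename).
"""

from __future__ import annotations

import logging
import os
import tempfile
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

from .clonality import ClonalityAssignment, ClonalityLabel
from .data import LabeledDataset
from .tcr import CellRecord, Chain, Tissue, parse_recombinant

logger = logging.getLogger("clonomark")

__all__ = [
    "read_expression",
    "write_expression_mtx",
    "write_expression_tsv",
    "read_tcr_table",
    "write_tcr_table",
    "read_cell_metadata",
    "apply_metadata",
    "cd8_flag_from_expression",
    "write_assignments",
    "read_labels",
    "write_labels",
    "read_config",
    "write_config",
    "atomic_write_text",
]


# ---------------------------------------------------------------------------
# atomic writing


def atomic_write_text(path, text: str) -> None:
    """Write text via a temp file and rename, so partial files never appear."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w") as fh:
            fh.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _atomic_df(df: pd.DataFrame, path, **kwargs) -> None:
    atomic_write_text(path, df.to_csv(sep="\t", index=False, **kwargs))


# ---------------------------------------------------------------------------
# expression matrices


def _dedupe(names: list[str], what: str) -> list[str]:
    seen: dict[str, int] = {}
    out = []
    for n in names:
        if n in seen:
            seen[n] += 1
            new = f"{n}.{seen[n]}"
            logger.info("deduplicated %s name %r -> %r", what, n, new)
            out.append(new)
        else:
            seen[n] = 0
            out.append(n)
    return out


def read_expression(
    path, *, orientation: str = "genes_by_cells"
) -> tuple[np.ndarray, list[str], list[str]]:
    """Read an expression matrix as (cells x genes, gene_names, cell_ids).

    ``path`` is either a dense TSV (header row of gene names, first column
    of cell ids) or a Matrix Market ``.mtx`` file with sidecars
    ``<stem>_genes.txt`` and ``<stem>_cells.txt`` (one name per line).
    Matrix Market files default to the community genes x cells orientation;
    pass ``orientation="cells_by_genes"`` if yours is transposed.
    Duplicate names are deduplicated with numeric suffixes.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"expression file not found: {path}")
    if path.suffix == ".mtx":
        genes_file = path.with_name(path.stem + "_genes.txt")
        cells_file = path.with_name(path.stem + "_cells.txt")
        for side in (genes_file, cells_file):
            if not side.exists():
                raise FileNotFoundError(f"missing sidecar name file: {side}")
        mat = scipy.io.mmread(path)
        mat = np.asarray(mat.todense() if scipy.sparse.issparse(mat) else mat, dtype=np.float64)
        genes = genes_file.read_text().split()
        cellids = cells_file.read_text().split()
        if orientation == "genes_by_cells":
            mat = mat.T
        elif orientation != "cells_by_genes":
            raise ValueError(f"unknown orientation {orientation!r}")
        n, g = mat.shape
        if len(cellids) != n or len(genes) != g:
            raise ValueError(
                f"{path}: matrix is {n} cells x {g} genes but sidecars name "
                f"{len(cellids)} cells and {len(genes)} genes"
            )
    else:
        df = pd.read_csv(path, sep="\t", index_col=0)
        mat = df.to_numpy(dtype=np.float64)
        genes = [str(c) for c in df.columns]
        cellids = [str(i) for i in df.index]
    return mat, _dedupe(genes, "gene"), _dedupe(cellids, "cell")


def write_expression_mtx(path, matrix: np.ndarray, gene_names, cell_ids) -> None:
    """Write genes x cells Matrix Market plus name sidecars."""
    path = Path(path)
    sparse = scipy.sparse.coo_matrix(np.asarray(matrix).T)
    with tempfile.NamedTemporaryFile(dir=path.parent, suffix=".mtx", delete=False) as fh:
        tmp = fh.name
    scipy.io.mmwrite(tmp, sparse)
    os.replace(tmp, path)
    atomic_write_text(path.with_name(path.stem + "_genes.txt"), "\n".join(gene_names) + "\n")
    atomic_write_text(path.with_name(path.stem + "_cells.txt"), "\n".join(cell_ids) + "\n")


def write_expression_tsv(path, matrix: np.ndarray, gene_names, cell_ids) -> None:
    df = pd.DataFrame(np.asarray(matrix), index=cell_ids, columns=gene_names)
    atomic_write_text(path, df.to_csv(sep="\t", index_label="cell_id"))


# ---------------------------------------------------------------------------
# TCR tables and metadata


def write_tcr_table(path, cells: list[CellRecord]) -> None:
    """One row per recombinant: cell_id, donor_id, tissue, chain, recombinant."""
    rows = []
    for c in cells:
        for chain, idents in (("A", sorted(c.alpha_set)), ("B", sorted(c.beta_set))):
            for ident in idents:
                rows.append(
                    {"cell_id": c.cell_id, "donor_id": c.donor_id,
                     "tissue": c.tissue.value, "chain": chain, "recombinant": ident}
                )
    _atomic_df(pd.DataFrame(rows, columns=["cell_id", "donor_id", "tissue", "chain", "recombinant"]), path)


def read_tcr_table(path) -> list[CellRecord]:
    """Read the recombinant table back into CellRecords (CD8 flag unset).

    Every recombinant string is validated through the template parser; the
    declared chain column must agree with the locus-name prefixes.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    required = {"cell_id", "donor_id", "chain", "recombinant"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing required columns {sorted(missing)}")
    cells: dict[str, dict] = {}
    for row in df.itertuples(index=False):
        rec = parse_recombinant(row.recombinant)
        declared = Chain.ALPHA if row.chain.upper() in ("A", "ALPHA") else Chain.BETA
        if rec.chain is not declared:
            raise ValueError(
                f"{path}: recombinant {row.recombinant!r} declared chain "
                f"{row.chain!r} but loci indicate {rec.chain.name}"
            )
        entry = cells.setdefault(
            row.cell_id,
            {"donor": row.donor_id,
             "tissue": getattr(row, "tissue", "SKIN"),
             "alpha": set(), "beta": set()},
        )
        (entry["alpha"] if rec.chain is Chain.ALPHA else entry["beta"]).add(rec.identifier)
    return [
        CellRecord(
            cell_id=cid,
            donor_id=e["donor"],
            tissue=Tissue(e["tissue"]) if e["tissue"] in Tissue.__members__ else Tissue.OTHER,
            alpha_set=frozenset(e["alpha"]),
            beta_set=frozenset(e["beta"]),
        )
        for cid, e in cells.items()
    ]


def read_cell_metadata(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if "cell_id" not in df.columns:
        raise ValueError(f"{path}: metadata needs a cell_id column")
    return df


def cd8_flag_from_expression(
    matrix: np.ndarray, gene_names: list[str], cell_ids: list[str], threshold: float = 1.0
) -> dict[str, bool]:
    """CD8 phenotype from expression: CD8A+CD8B above ``threshold``."""
    idx = [i for i, g in enumerate(gene_names) if g.upper() in ("CD8A", "CD8B")]
    if not idx:
        raise ValueError("neither CD8A nor CD8B found in gene names")
    total = np.asarray(matrix)[:, idx].sum(axis=1)
    return {cid: bool(t > threshold) for cid, t in zip(cell_ids, total)}


def apply_metadata(
    cells: list[CellRecord],
    meta: pd.DataFrame | None = None,
    cd8_col: str | None = None,
    cd8_flags: dict[str, bool] | None = None,
) -> list[CellRecord]:
    """Return copies of ``cells`` with CD8 flags filled in from metadata or
    a precomputed flag mapping."""
    lookup: dict[str, bool] = {}
    if meta is not None and cd8_col is not None:
        if cd8_col not in meta.columns:
            raise ValueError(f"metadata has no column {cd8_col!r}")
        truthy = {"1", "true", "yes", "y", "pos", "positive"}
        lookup = {
            str(r["cell_id"]): str(r[cd8_col]).strip().lower() in truthy
            for _, r in meta.iterrows()
        }
    if cd8_flags:
        lookup.update(cd8_flags)
    return [
        CellRecord(
            cell_id=c.cell_id, donor_id=c.donor_id, tissue=c.tissue,
            alpha_set=c.alpha_set, beta_set=c.beta_set,
            cd8_positive=lookup.get(c.cell_id, c.cd8_positive),
        )
        for c in cells
    ]


# ---------------------------------------------------------------------------
# assignments / labels


def write_assignments(path, assignments: list[ClonalityAssignment]) -> None:
    df = pd.DataFrame(
        [
            {
                "cell_id": a.cell_id,
                "donor_id": a.donor_id,
                "label": a.label.value,
                "malignancy_target": "" if a.malignancy_target is None else a.malignancy_target,
                "dominant_alpha": a.dominant_alpha or "",
                "dominant_beta": a.dominant_beta or "",
            }
            for a in assignments
        ]
    )
    _atomic_df(df, path)


def read_labels(path) -> pd.DataFrame:
    """Read a label table (cell_id, donor_id, malignancy_target at minimum)."""
    df = pd.read_csv(path, sep="\t", dtype={"cell_id": str, "donor_id": str})
    needed = {"cell_id", "donor_id", "malignancy_target"}
    missing = needed - set(df.columns)
    if missing:
        raise ValueError(f"{path}: label table missing columns {sorted(missing)}")
    df = df[df["malignancy_target"].astype(str).str.len() > 0].copy()
    df["malignancy_target"] = df["malignancy_target"].astype(int)
    return df


def write_labels(path, dataset: LabeledDataset) -> None:
    df = pd.DataFrame(
        {"cell_id": dataset.cell_ids, "donor_id": dataset.donor_ids,
         "malignancy_target": dataset.targets}
    )
    _atomic_df(df, path)


def dataset_from_files(expression_path, labels_path, *, orientation="genes_by_cells") -> LabeledDataset:
    """Join an expression matrix with a label table into a LabeledDataset,
    keeping only labelled cells (in expression order)."""
    matrix, genes, cellids = read_expression(expression_path, orientation=orientation)
    labels = read_labels(labels_path).set_index("cell_id")
    keep = [i for i, cid in enumerate(cellids) if cid in labels.index]
    if not keep:
        raise ValueError(f"no cell ids shared between {expression_path} and {labels_path}")
    cellids_kept = [cellids[i] for i in keep]
    return LabeledDataset(
        matrix=matrix[keep],
        gene_names=genes,
        cell_ids=cellids_kept,
        donor_ids=[str(labels.loc[c, "donor_id"]) for c in cellids_kept],
        targets=np.array([int(labels.loc[c, "malignancy_target"]) for c in cellids_kept]),
    )


# ---------------------------------------------------------------------------
# key = value configuration


def read_config(path) -> dict[str, str]:
    """Parse a plain-text ``key = value`` file; '#' starts a comment."""
    out: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected 'key = value', got {line!r}")
        key, value = line.split("=", 1)
        out[key.strip()] = value.strip()
    return out


def write_config(path, values: dict) -> None:
    atomic_write_text(path, "".join(f"{k} = {v}\n" for k, v in values.items()))
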