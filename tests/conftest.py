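import numpy as np

from clonomark import CellRecord


def make_cell(cell_id, donor="d1", alphas=(), betas=(), cd8=False):
    return CellRecord(
        cell_id=cell_id,
        donor_id=donor,
        alpha_set=frozenset(alphas),
        beta_set=frozenset(betas),
        cd8_positive=cd8,
    )


def random_repertoire(rng, n_cells, donor="d1", n_alpha=6, n_beta=6):
    """Small random repertoire with overlapping chain draws, incl. chain-less
    combinations avoided (every cell keeps at least one chain)."""
    alphas = [f"a{i}" for i in range(n_alpha)]
    betas = [f"b{i}" for i in range(n_beta)]
    cells = []
    for i in range(n_cells):
        na = int(rng.integers(0, 3))
        nb = int(rng.integers(0, 3))
        if na == 0 and nb == 0:
            na = 1
        a = rng.choice(alphas, size=na, replace=False) if na else []
        b = rng.choice(betas, size=nb, replace=False) if nb else []
        cells.append(make_cell(f"{donor}c{i}", donor=donor, alphas=a, betas=b))
    return cells
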