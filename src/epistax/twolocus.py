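"""Two-locus penetrance models: balanced penetrance, discretization to
fully-penetrant binary tables, and canonical symmetry classification.

A fully-penetrant model is a 3x3 binary table over the genotype
combinations of a pair.  Two tables are equivalent when related by locus
swap (transpose) or an allele flip at either locus (row/column reversal);
optionally also by exchanging high/low risk status (0/1 complementation).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from epistax.pairscan import PairTable


@dataclass
class BalancedPenetranceTable:
    """Per-cell balanced sample penetrance p1 / (p1 + p0).

    ``p_iv`` is the within-class proportional frequency of cell v, so the
    value is 0.5 wherever case and control distributions agree, making
    tables comparable across datasets.  Unoccupied cells are NaN.
    """

    values: np.ndarray
    occupied: np.ndarray
    case_freq: np.ndarray = field(repr=False, default=None)
    ctrl_freq: np.ndarray = field(repr=False, default=None)


def balanced_penetrance(table: PairTable) -> BalancedPenetranceTable:
    """Balanced penetrance of each of the 9 genotype-combination cells."""
    if table.n_cases == 0 or table.n_controls == 0:
        raise ValueError("both phenotype classes must be non-empty")
    p1 = table.counts[1].reshape(3, 3) / table.n_cases
    p0 = table.counts[0].reshape(3, 3) / table.n_controls
    occ = (p1 > 0) | (p0 > 0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(occ, p1 / (p1 + p0), np.nan)
    return BalancedPenetranceTable(values=values, occupied=occ, case_freq=p1, ctrl_freq=p0)


# ---------------------------------------------------------------------------
# fully penetrant models and their symmetry classes
# ---------------------------------------------------------------------------


def _cells_to_code(cells: np.ndarray) -> int:
    """Row-major binary encoding; cell (0,0) is the most significant bit."""
    flat = np.asarray(cells, dtype=int).reshape(9)
    code = 0
    for bit in flat:
        code = (code << 1) | int(bit)
    return code


def _code_to_cells(code: int) -> np.ndarray:
    bits = [(code >> (8 - i)) & 1 for i in range(9)]
    return np.array(bits, dtype=np.int8).reshape(3, 3)


def _orbit_codes(cells: np.ndarray, include_complement: bool):
    tables = [cells, 1 - cells] if include_complement else [cells]
    for t in tables:
        for a in (t, t.T):
            for b in (a, a[::-1, :]):
                for c in (b, b[:, ::-1]):
                    yield _cells_to_code(c)


@dataclass
class FullPenetranceModel:
    """A 3x3 binary risk table with its canonical class representative."""

    cells: np.ndarray
    include_complement: bool = False
    named_label: str | None = None

    def __post_init__(self) -> None:
        self.cells = np.asarray(self.cells, dtype=np.int8)
        if self.cells.shape != (3, 3) or not np.isin(self.cells, [0, 1]).all():
            raise ValueError("cells must be a binary 3x3 table")

    @property
    def code(self) -> int:
        return _cells_to_code(self.cells)

    @property
    def class_id(self) -> int:
        return canonical_class(self, include_complement=self.include_complement)


def canonical_class(model, include_complement: bool = False) -> int:
    """Minimum code over the symmetry orbit of a model.

    The group is generated by transpose, row reversal and column reversal
    (order 8); with ``include_complement`` also 0/1 exchange (order 16).
    """
    cells = model.cells if isinstance(model, FullPenetranceModel) else np.asarray(model)
    return min(_orbit_codes(cells, include_complement))


def discretize(
    bp: BalancedPenetranceTable,
    table: PairTable,
    rare_freq: float = 0.01,
    include_complement: bool = False,
) -> FullPenetranceModel:
    """Binarize balanced penetrance into a fully-penetrant model.

    Cells with within-class frequency below ``rare_freq`` in BOTH cases and
    controls are low risk; remaining cells are high risk iff balanced
    penetrance exceeds 0.5 (the no-association point of the balanced
    scale).
    """
    p1 = table.counts[1].reshape(3, 3) / max(table.n_cases, 1)
    p0 = table.counts[0].reshape(3, 3) / max(table.n_controls, 1)
    rare = (p1 < rare_freq) & (p0 < rare_freq)
    with np.errstate(invalid="ignore"):
        high = np.where(rare, 0, np.nan_to_num(bp.values) > 0.5).astype(np.int8)
    return FullPenetranceModel(cells=high, include_complement=include_complement)


def enumerate_classes(include_complement: bool = False) -> dict[int, list[int]]:
    """Orbits of all 512 binary tables; maps class_id -> member codes."""
    orbits: dict[int, list[int]] = {}
    for code in range(512):
        cid = canonical_class(_code_to_cells(code), include_complement)
        orbits.setdefault(cid, []).append(code)
    return orbits


def count_classes(include_complement: bool = False, exclude_constant: bool = True) -> int:
    """Number of symmetry classes of fully-penetrant models.

    Without complementation the two constant tables form two classes (100
    remain when excluded); with it they merge into one (50 remain).
    """
    orbits = enumerate_classes(include_complement)
    n = len(orbits)
    if exclude_constant:
        constant = {canonical_class(_code_to_cells(c), include_complement) for c in (0, 511)}
        n -= len(constant)
    return n


def class_distribution(
    models: list[FullPenetranceModel],
    ranks=None,
    k_grid=None,
) -> pd.DataFrame:
    """Cumulative class frequencies among the top-k models by significance.

    ``ranks`` orders the models (best first); rows are k values, columns
    canonical class ids, entries the fraction of the top-k in each class.
    """
    if not models:
        raise ValueError("empty model list")
    order = np.argsort(ranks) if ranks is not None else np.arange(len(models))
    cids = np.array([models[i].class_id for i in order])
    if k_grid is None:
        k_grid = range(1, len(models) + 1)
    classes = sorted(set(cids))
    rows = {}
    for k in k_grid:
        k = min(k, len(cids))
        top = cids[:k]
        rows[k] = [float((top == c).mean()) for c in classes]
    return pd.DataFrame.from_dict(rows, orient="index", columns=classes)
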