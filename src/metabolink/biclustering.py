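"""Qualitative biclustering of the thresholded microbe × drug score matrix.

The continuous score matrix (cell = best pair score between a microbe's
metabolites and a drug, zeroed below a cutoff) is discretized into integer
symbols in {−r, …, 0, …, +r} and mined for *biclusters*: submatrices whose
member rows carry the same nonzero symbol in (almost) every member column.
The consistency of a block is the minimum over its columns of the largest
fraction of member rows agreeing on one nonzero symbol; a run's ``c``
parameter lower-bounds it.

The algorithm is a seed-and-expand greedy search: rows are connected by
edges weighted by the number of columns where they carry identical nonzero
symbols; edges are processed in decreasing weight as seeds, each expanded by
greedily adding rows (while consistency stays >= c) and then columns (whose
dominant nonzero symbol is shared by >= c of member rows) until a fixpoint.
Blocks are deduplicated, sorted by size, and filtered for overlap.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class QualitativeMatrix:
    """Discretized matrix with integer symbols bounded by a declared rank r."""

    symbols: pd.DataFrame  # int entries in {-r..r}; index=row ids, columns=col ids
    r: int

    def __post_init__(self) -> None:
        vals = self.symbols.to_numpy()
        if vals.size and int(np.abs(vals).max()) > self.r:
            raise ValueError("symbol magnitude exceeds declared rank r")

    @property
    def row_ids(self) -> list[str]:
        return list(self.symbols.index)

    @property
    def col_ids(self) -> list[str]:
        return list(self.symbols.columns)


@dataclass(frozen=True)
class Bicluster:
    """A consistent submatrix: row ids, column ids and their agreement level."""

    rows: tuple[str, ...]
    cols: tuple[str, ...]
    consistency: float

    def __post_init__(self) -> None:
        if len(self.rows) < 2 or len(self.cols) < 2:
            raise ValueError("a bicluster needs at least 2 rows and 2 columns")

    @property
    def size(self) -> int:
        return len(self.rows) * len(self.cols)

    @property
    def cells(self) -> frozenset[tuple[str, str]]:
        return frozenset((r, c) for r in self.rows for c in self.cols)


def build_score_matrix(
    pairs: pd.DataFrame,
    microbes: Sequence,
    cutoff: float = 0.6,
) -> pd.DataFrame:
    """Aggregate the pair table into a thresholded microbe × drug matrix.

    Cell (m, d) is the maximum pair score over microbe m's metabolites
    against drug d; cells below ``cutoff`` are zeroed.  Every metabolite in
    the pair table must belong to at least one microbe.
    """
    met_to_microbes: dict[str, list[str]] = {}
    for mic in microbes:
        for met in mic.metabolite_ids:
            met_to_microbes.setdefault(met, []).append(mic.microbe_id)
    orphans = sorted(set(pairs["metabolite_id"]) - set(met_to_microbes))
    if orphans:
        raise ValueError(f"metabolites belong to no microbe: {', '.join(orphans)}")

    microbe_ids = [m.microbe_id for m in microbes]
    drug_ids = sorted(pairs["drug_id"].unique())
    mat = pd.DataFrame(0.0, index=microbe_ids, columns=drug_ids)
    for met, d, score in zip(pairs["metabolite_id"], pairs["drug_id"], pairs["score"]):
        for mic in met_to_microbes[met]:
            if score > mat.at[mic, d]:
                mat.at[mic, d] = score
    mat[mat < cutoff] = 0.0
    return mat


def discretize(matrix: pd.DataFrame, r: int = 1, q: float = 0.06) -> QualitativeMatrix:
    """Map a real matrix to integer symbols per row.

    In each row, the ``floor(q * n_cols)`` largest values get positive
    symbols (+1…+r by equal sub-quantiles, the most extreme values carrying
    +r), the same number of smallest values get the mirrored negative
    symbols, and the remainder is 0.  A matrix that is already binary in
    {0, 1} passes through unchanged as {0, +1} symbols.  Constant rows and
    rows where ``q * n_cols < 1`` come out all-zero (the latter with a
    warning).
    """
    if r < 1:
        raise ValueError("r must be >= 1")
    if not 0.0 < q < 0.5:
        raise ValueError("q must lie in (0, 0.5)")
    vals = matrix.to_numpy(dtype=float)
    if not np.all(np.isfinite(vals)):
        raise ValueError("matrix must be finite")
    if np.isin(vals, (0.0, 1.0)).all():
        return QualitativeMatrix(symbols=matrix.astype(int), r=r)

    n_cols = matrix.shape[1]
    k = int(q * n_cols)
    sym = np.zeros(matrix.shape, dtype=int)
    if k < 1:
        log.warning("q*n_cols = %.3f < 1: all rows discretize to zero", q * n_cols)
    else:
        # level of the i-th most extreme value (i = 0..k-1): +r down to +1
        levels = np.array([r - (i * r) // k for i in range(k)])
        for ri in range(matrix.shape[0]):
            row = vals[ri]
            if row.max() == row.min():
                continue  # no extremes in a constant row
            order_desc = np.lexsort((np.arange(n_cols), -row))
            order_asc = np.lexsort((np.arange(n_cols), row))
            sym[ri, order_desc[:k]] = levels
            sym[ri, order_asc[:k]] = -levels
    return QualitativeMatrix(
        symbols=pd.DataFrame(sym, index=matrix.index, columns=matrix.columns), r=r
    )


def block_consistency(
    qm: QualitativeMatrix, rows: Sequence[str], cols: Sequence[str]
) -> float:
    """Min over columns of the best nonzero-symbol agreement fraction."""
    sub = qm.symbols.loc[list(rows), list(cols)].to_numpy()
    worst = 1.0
    for j in range(sub.shape[1]):
        col = sub[:, j]
        nz = col[col != 0]
        if nz.size == 0:
            return 0.0
        _, counts = np.unique(nz, return_counts=True)
        worst = min(worst, counts.max() / len(col))
    return worst


def _dominant_symbol(col: np.ndarray) -> tuple[int, int]:
    """(symbol, count) of the most frequent nonzero symbol; (0, 0) if none."""
    nz = col[col != 0]
    if nz.size == 0:
        return 0, 0
    syms, counts = np.unique(nz, return_counts=True)
    i = int(np.argmax(counts))
    return int(syms[i]), int(counts[i])


def _expand(
    S: np.ndarray,
    row_ids: list[str],
    col_ids: list[str],
    seed_rows: set[int],
    seed_cols: set[int],
    c: float,
) -> tuple[set[int], set[int]]:
    """Grow a seed block to its greedy fixpoint at consistency >= c."""
    rows, cols = set(seed_rows), set(seed_cols)
    changed = True
    while changed:
        changed = False
        # candidate row maximizing agreement with the dominant symbol per column
        col_list = sorted(cols)
        sub = S[np.ix_(sorted(rows), col_list)]
        dom = [_dominant_symbol(sub[:, j_idx])[0] for j_idx in range(len(col_list))]
        best: Optional[tuple[int, str, int]] = None  # (-agreement, row_id, row idx)
        for i in range(S.shape[0]):
            if i in rows:
                continue
            agree = sum(
                1 for j_idx, j in enumerate(col_list)
                if dom[j_idx] != 0 and S[i, j] == dom[j_idx]
            )
            # a member row must itself agree on >= c of the block columns;
            # otherwise zero-heavy rows could join on consistency slack alone
            if agree < c * len(col_list):
                continue
            key = (-agree, row_ids[i], i)
            if best is None or key < best:
                best = key
        if best is not None:
            i = best[2]
            trial = sorted(rows | {i})
            if _consistency_idx(S, trial, col_list) >= c:
                rows.add(i)
                changed = True
        # columns whose dominant nonzero symbol covers >= c of member rows
        row_list = sorted(rows)
        for j in range(S.shape[1]):
            if j in cols:
                continue
            _, count = _dominant_symbol(S[row_list, j])
            if count >= c * len(row_list) and count >= 1:
                cols.add(j)
                changed = True
    return rows, cols


def _consistency_idx(S: np.ndarray, rows: Sequence[int], cols: Sequence[int]) -> float:
    worst = 1.0
    for j in cols:
        _, count = _dominant_symbol(S[list(rows), j])
        if count == 0:
            return 0.0
        worst = min(worst, count / len(rows))
    return worst


def qubic(
    qm: QualitativeMatrix,
    c: float = 0.95,
    o: int = 100,
    f: float = 1.0,
) -> list[Bicluster]:
    """Mine biclusters from a qualitative matrix.

    Parameters
    ----------
    c
        Minimum block consistency in (0.5, 1].
    o
        Maximum number of blocks reported.
    f
        Overlap tolerance: a block is reported only if its cell overlap
        with every previously reported block is at most ``f`` of its own
        cells (``f=0`` forbids any overlap; duplicates are always dropped).

    Returns blocks of at least 2×2 sorted by size descending (ties broken by
    row/column ids), deterministically for a fixed input.
    """
    if not 0.5 < c <= 1.0:
        raise ValueError("c must lie in (0.5, 1]")
    if o < 1:
        raise ValueError("o must be >= 1")
    if not 0.0 <= f <= 1.0:
        raise ValueError("f must lie in [0, 1]")
    S = qm.symbols.to_numpy()
    row_ids, col_ids = qm.row_ids, qm.col_ids
    n_rows = S.shape[0]

    # seed edges: row pairs weighted by identical-nonzero-symbol column count
    order = sorted(range(n_rows), key=lambda i: row_ids[i])
    edges: list[tuple[int, str, str, int, int]] = []
    for a_pos in range(len(order)):
        for b_pos in range(a_pos + 1, len(order)):
            i, j = order[a_pos], order[b_pos]
            w = int(np.sum((S[i] == S[j]) & (S[i] != 0)))
            if w >= 2:
                edges.append((-w, row_ids[i], row_ids[j], i, j))
    edges.sort()

    candidates: list[Bicluster] = []
    seen: set[tuple[tuple[str, ...], tuple[str, ...]]] = set()
    for _, _, _, i, j in edges:
        seed_cols = {int(k) for k in np.nonzero((S[i] == S[j]) & (S[i] != 0))[0]}
        rows, cols = _expand(S, row_ids, col_ids, {i, j}, seed_cols, c)
        if len(rows) < 2 or len(cols) < 2:
            continue
        if _consistency_idx(S, sorted(rows), sorted(cols)) < c:
            continue
        r_ids = tuple(sorted(row_ids[x] for x in rows))
        c_ids = tuple(sorted(col_ids[x] for x in cols))
        if (r_ids, c_ids) in seen:
            continue
        seen.add((r_ids, c_ids))
        candidates.append(
            Bicluster(rows=r_ids, cols=c_ids,
                      consistency=_consistency_idx(S, sorted(rows), sorted(cols)))
        )

    candidates.sort(key=lambda b: (-b.size, b.rows, b.cols))
    accepted: list[Bicluster] = []
    for b in candidates:
        if len(accepted) >= o:
            break
        cells = b.cells
        ok = True
        for prev in accepted:
            overlap = len(cells & prev.cells)
            if overlap == len(cells) or overlap > f * len(cells):
                ok = False
                break
        if ok:
            accepted.append(b)
    return accepted


def format_blocks(blocks: Sequence[Bicluster]) -> str:
    """Human-readable block text, one block per line group."""
    lines = []
    for i, b in enumerate(blocks, start=1):
        lines.append(
            f"BC{i:03d}\trows [{len(b.rows)}]: {' '.join(b.rows)}\t"
            f"cols [{len(b.cols)}]: {' '.join(b.cols)}\t"
            f"consistency: {b.consistency:.4f}"
        )
    return "\n".join(lines) + ("\n" if lines else "")
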