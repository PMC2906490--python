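"""Greedy seed-row matrix seriation under the l1 norm.

Rows are reordered so that similar rows sit next to each other: the row with
the maximal value-sum (the seed row) is placed first, then the algorithm
repeatedly appends the remaining row with the smallest l1 distance to the
last placed row. The same pass is then applied to the columns of the
row-reordered matrix. The procedure is deterministic (ties broken by lowest
original index), runs in quadratic time, and is a heuristic seriation — a
useful starting point for visual analysis, not an optimal ordering.

Masked (NaN) cells contribute 0 to row sums, and masked positions contribute
0 to l1 distances, so the algorithm is total on filtered matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError


@dataclass
class SortResult:
    """Row/column permutations (0-based original indices) and the reordered matrix.

    ``sorted_matrix[a, b] == original[row_order[a], col_order[b]]``; exported
    triple files use the original 1-based labels so residue identity survives
    sorting.
    """

    row_order: np.ndarray
    col_order: np.ndarray
    sorted_matrix: np.ndarray = field(repr=False)


def find_seed_row(m: np.ndarray) -> int:
    """Index of the row with maximal value-sum; ties broken by lowest index."""
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.size == 0:
        raise InputError("seed row requires a non-empty 2-D matrix")
    sums = np.nan_to_num(m, nan=0.0).sum(axis=1)
    return int(np.argmax(sums))


def l1_distance(a, b) -> float:
    """Sum of absolute componentwise differences; masked positions contribute 0."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise InputError(f"vector length mismatch: {a.shape} vs {b.shape}")
    return float(np.nan_to_num(np.abs(a - b), nan=0.0).sum())


def sort_rows(m: np.ndarray) -> np.ndarray:
    """Greedy seed-row ordering of the rows; returns 0-based original indices.

    The first element is the seed row; each subsequent element is the
    remaining row minimizing l1 distance to the previously placed row, ties
    by lowest original index.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2 or m.shape[0] < 1:
        raise InputError("sorting requires a matrix with at least one row")
    n = m.shape[0]
    order = [find_seed_row(m)]
    remaining = np.ones(n, dtype=bool)
    remaining[order[0]] = False
    while remaining.any():
        cur = m[order[-1]]
        idx = np.nonzero(remaining)[0]  # ascending: argmin tie-breaks low index
        dists = np.nan_to_num(np.abs(m[idx] - cur), nan=0.0).sum(axis=1)
        nxt = idx[int(np.argmin(dists))]
        order.append(int(nxt))
        remaining[nxt] = False
    return np.asarray(order, dtype=np.intp)


def sort_matrix(m: np.ndarray) -> SortResult:
    """Row pass on the original matrix, then column pass on the row-reordered one.

    The passes are sequential and independent; for symmetric matrices the two
    permutations can differ — no symmetry-preserving coupling is applied.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise InputError("sorting requires a 2-D matrix")
    row_order = sort_rows(m)
    by_rows = m[row_order]
    col_order = sort_rows(by_rows.T)
    return SortResult(row_order=row_order, col_order=col_order,
                      sorted_matrix=by_rows[:, col_order])
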