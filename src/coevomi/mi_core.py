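"""Column entropies, joint entropies, and the mutual-information matrix.

For alignment columns i and j with observed (plug-in) symbol frequencies
p_i(x), p_j(y), p_ij(x, y), the mutual information is computed in the
entropy-difference form

    MI_ij = H_i + H_j - H_ij,

where H is the Shannon entropy of the respective frequency table. Applied to
every pair of columns this yields a symmetric L x L matrix whose diagonal
holds the single-column entropies (MI of a column with itself). Entropies are
reported in bits by default; any other logarithm base is a pure rescaling and
cancels in downstream Z-scores.

No small-sample bias correction is applied to the plug-in estimates: the
finite-size bias of MI at realistic sequence counts (~10^2 sequences against
a 22-symbol alphabet) is handled downstream by the column-shuffle null model,
not by estimator correction. Gap and non-standard symbols count as ordinary
symbols — the alphabet is extended rather than the data filtered.
"""

from __future__ import annotations

import math

import numpy as np
from scipy.stats import entropy as _scipy_entropy

from .errors import InputError
from .msa_io import ALPHABET_SIZE, Alignment, as_codes

_LN2 = math.log(2.0)


def _base_factor(base: float) -> float:
    """Conversion factor from bits to the requested logarithm base."""
    if base <= 0 or base == 1:
        raise InputError(f"invalid logarithm base {base}")
    return _LN2 / math.log(base)


def column_entropy(col, base: float = 2.0) -> float:
    """Shannon entropy of one column's observed symbol frequencies.

    The 0 * log 0 convention is applied to unobserved symbols; the result
    lies in [0, log_base 22].
    """
    codes = as_codes(col)
    if codes.size == 0:
        raise InputError("empty column")
    _, counts = np.unique(codes, return_counts=True)
    return float(_scipy_entropy(counts, base=base))


def joint_entropy(col_i, col_j, base: float = 2.0) -> float:
    """Shannon entropy of the observed pair frequencies of two columns."""
    ci, cj = as_codes(col_i), as_codes(col_j)
    if ci.size == 0:
        raise InputError("empty column")
    if ci.size != cj.size:
        raise InputError(f"column length mismatch: {ci.size} vs {cj.size}")
    fused = ci.astype(np.int64) * ALPHABET_SIZE + cj
    _, counts = np.unique(fused, return_counts=True)
    return float(_scipy_entropy(counts, base=base))


def mutual_information(col_i, col_j, base: float = 2.0, clamp: bool = True) -> float:
    """MI between two columns via the entropy-difference form.

    The plug-in value is mathematically non-negative; floating-point
    cancellation can leave a tiny negative residue, which is clamped to 0
    unless ``clamp=False`` (the raw value is what the null-model Z-scores
    consume, keeping observed and null on the same footing).
    """
    mi = (column_entropy(col_i, base) + column_entropy(col_j, base)
          - joint_entropy(col_i, col_j, base))
    return max(0.0, mi) if clamp else mi


def _entropies_from_counts(counts: np.ndarray, n: int) -> np.ndarray:
    """Row-wise entropy in bits of a (m, k) table of counts summing to n."""
    p = counts / n
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(counts > 0, p * np.log2(p), 0.0)
    return -terms.sum(axis=-1)


def _column_entropies(codes: np.ndarray) -> np.ndarray:
    n, L = codes.shape
    counts = np.zeros((L, ALPHABET_SIZE), dtype=np.int64)
    for c in range(ALPHABET_SIZE):
        counts[:, c] = (codes == c).sum(axis=0)
    return _entropies_from_counts(counts, n)


def _joint_entropy_matrix(codes: np.ndarray) -> np.ndarray:
    """All pairwise joint entropies (bits) of an (n, L) code matrix.

    Pair frequencies for a fixed left column against every right column are
    accumulated in one fused bincount, so the work per matrix is L vectorized
    passes rather than L(L+1)/2 scalar ones.
    """
    n, L = codes.shape
    wide = codes.astype(np.intp)
    H = np.zeros((L, L))
    k2 = ALPHABET_SIZE * ALPHABET_SIZE
    for i in range(L):
        block = wide[:, i, None] * ALPHABET_SIZE + wide[:, i:]
        block = block + np.arange(L - i) * k2
        counts = np.bincount(block.ravel(), minlength=(L - i) * k2)
        counts = counts.reshape(L - i, k2)
        H[i, i:] = _entropies_from_counts(counts, n)
        H[i:, i] = H[i, i:]
    return H


def mi_matrix(aln: Alignment, base: float = 2.0, clamp: bool = True) -> np.ndarray:
    """Symmetric L x L mutual-information matrix of an alignment.

    Each unique pair (i <= j) is computed once and mirrored; the diagonal
    holds the column entropies H_i. With ``clamp=False`` tiny negative
    floating-point residues are preserved (used by the null model).
    """
    codes = aln.codes
    h = _column_entropies(codes)
    values = h[:, None] + h[None, :] - _joint_entropy_matrix(codes)
    np.fill_diagonal(values, h)
    if clamp:
        np.maximum(values, 0.0, out=values)
    factor = _base_factor(base)
    if factor != 1.0:
        values *= factor
    return values


def pair_count(L: int) -> int:
    """Number of unique column pairs (i, j) with i <= j, self-pairs included."""
    if L < 1:
        raise InputError(f"column count must be >= 1, got {L}")
    return L * (L + 1) // 2
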