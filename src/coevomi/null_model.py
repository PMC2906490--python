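"""Column-shuffle null model and Z-score normalization.

Plug-in MI estimates carry an upward finite-sample bias that grows as the
number of sequences shrinks relative to the 22-symbol alphabet. The remedy
implemented here is an empirical null of neutral (uncorrelated) evolution:
each alignment column is independently permuted across sequences, which
preserves every single-column entropy exactly while destroying all
inter-column correlation. Repeating the shuffle gives, for every column pair
(i, j) independently, a sample of null MI values with mean <MI_ij> and
standard deviation sigma(MI_ij), and the observed value is standardized as

    Z_ij = (MI_ij - <MI_ij>) / sigma(MI_ij).

Pairs whose null standard deviation is exactly zero (e.g. any pair involving
a constant column, and the diagonal) have no defined Z and are masked rather
than propagated as infinities. Z is invariant under a change of entropy
logarithm base, since MI, the null mean and the null deviation all rescale
by the same factor.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InputError
from .mi_core import mi_matrix
from .msa_io import Alignment, as_codes

DEFAULT_REPLICATES = 100


def shuffle_column(col, rng: np.random.Generator) -> np.ndarray:
    """Uniform random permutation of a column's entries.

    The symbol multiset — hence the column entropy — is conserved exactly.
    """
    codes = as_codes(col)
    if codes.size == 0:
        raise InputError("empty column")
    return rng.permutation(codes)


@dataclass
class NullStats:
    """Per-pair sample statistics of MI over shuffle replicates."""

    mean: np.ndarray = field(repr=False)  # (L, L), bits (or chosen base)
    std: np.ndarray = field(repr=False)   # (L, L), same units, >= 0
    n_replicates: int
    seed: int | None


@dataclass
class ZMatrix:
    """Z-scores of observed MI against the shuffle null.

    ``values`` is NaN wherever ``undefined_mask`` is True (null sigma = 0).
    """

    values: np.ndarray = field(repr=False)
    undefined_mask: np.ndarray = field(repr=False)


def _shuffled_codes(codes: np.ndarray, replicate_seed: np.random.SeedSequence) -> np.ndarray:
    """Independently permute every column, one spawned RNG stream per column.

    Per-column streams make the result independent of column iteration order.
    """
    n, L = codes.shape
    out = np.empty_like(codes)
    for c, child in enumerate(replicate_seed.spawn(L)):
        rng = np.random.default_rng(child)
        out[:, c] = rng.permutation(codes[:, c])
    return out


def sample_null(aln: Alignment, n_replicates: int = DEFAULT_REPLICATES,
                seed: int | None = None, base: float = 2.0) -> NullStats:
    """Sample the shuffle null: per-pair mean and standard deviation of MI.

    Per replicate ALL columns are independently re-permuted and the full MI
    matrix recomputed (raw, unclamped values). Statistics use the unbiased
    n-1 denominator, so at least 2 replicates are required. Identical
    (alignment, n_replicates, seed) inputs give bit-identical results.
    """
    if n_replicates < 2:
        raise InputError(
            f"need >= 2 shuffle replicates for a sample standard deviation, "
            f"got {n_replicates}"
        )
    master = np.random.SeedSequence(seed)
    L = aln.n_columns
    # Welford accumulation: exact zero variance for constant samples (e.g. the
    # diagonal, whose MI is the shuffle-invariant column entropy), so the
    # sigma == 0 mask downstream is exact rather than cancellation noise.
    mean = np.zeros((L, L))
    m2 = np.zeros((L, L))
    for k, rep_seed in enumerate(master.spawn(n_replicates), start=1):
        shuffled = Alignment(ids=aln.ids, codes=_shuffled_codes(aln.codes, rep_seed))
        mi = mi_matrix(shuffled, base=base, clamp=False)
        delta = mi - mean
        mean += delta / k
        m2 += delta * (mi - mean)
    std = np.sqrt(np.maximum(m2, 0.0) / (n_replicates - 1))
    return NullStats(mean=mean, std=std, n_replicates=n_replicates, seed=seed)


def z_scores(mi: np.ndarray, null: NullStats) -> ZMatrix:
    """Standardize an MI matrix against the shuffle null, per pair.

    Cells with zero null standard deviation are masked (NaN), never infinite.
    """
    mi = np.asarray(mi, dtype=float)
    if mi.shape != null.mean.shape:
        raise InputError(
            f"MI matrix shape {mi.shape} does not match null shape {null.mean.shape}"
        )
    undefined = null.std == 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (mi - null.mean) / null.std
    z[undefined] = np.nan
    return ZMatrix(values=z, undefined_mask=undefined)
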