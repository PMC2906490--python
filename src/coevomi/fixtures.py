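"""Synthetic alignments with controlled co-evolutionary structure.

Columns are drawn iid from a background symbol distribution, except for
designated coupled pairs (i, j): there, each sequence's symbol at j is, with
probability ``coupling``, a fixed bijective image of its symbol at i (a
cyclic shift over the background support) and otherwise an independent
background draw. This probabilistic-relabeling mechanism is deliberately the
simplest one with a closed-form joint distribution — coupling 1 makes column
j a deterministic relabeling of column i (MI equals the column entropy),
coupling 0 makes the columns independent — so parameter-recovery tests have
an exact population-MI oracle. No claim of biological realism (no phylogeny,
no substitution model) is made.

The default background is uniform over a reduced 4-symbol alphabet
{A, C, D, E}: high per-column entropy (2 bits) with fast convergence of the
plug-in estimates; full 22-symbol backgrounds are supported.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np

from .errors import InputError
from .msa_io import Alignment, encode_symbol

#: Uniform background over a reduced high-entropy alphabet.
DEFAULT_BACKGROUND = {"A": 0.25, "C": 0.25, "D": 0.25, "E": 0.25}


def _normalize_background(background) -> tuple[list[str], np.ndarray]:
    """Coerce a background spec (mapping or symbol sequence) to (symbols, probs)."""
    if background is None:
        background = DEFAULT_BACKGROUND
    if isinstance(background, Mapping):
        symbols = list(background.keys())
        probs = np.asarray([background[s] for s in symbols], dtype=float)
    else:
        symbols = list(background)
        probs = np.ones(len(symbols))
    if len(symbols) == 0:
        raise InputError("background distribution is empty")
    if len(set(symbols)) != len(symbols):
        raise InputError("background symbols must be distinct")
    if (probs < 0).any() or probs.sum() <= 0:
        raise InputError("background probabilities must be non-negative, sum > 0")
    return symbols, probs / probs.sum()


def _bijection(k: int) -> np.ndarray:
    """The fixed coupling bijection on support indices: cyclic shift by one."""
    return (np.arange(k) + 1) % k


@dataclass
class CouplingSpec:
    """A planted coevolving column pair.

    ``pair`` holds 1-based alignment positions (i, j); ``coupling`` in [0, 1]
    is the probability that the symbol at j is the bijective image of the
    symbol at i. ``background`` optionally overrides the alignment-wide
    distribution for this pair's draws.
    """

    pair: tuple[int, int]
    coupling: float
    background: Mapping[str, float] | Sequence[str] | None = None

    def __post_init__(self):
        i, j = self.pair
        if i == j:
            raise InputError(f"coupled positions must differ, got ({i}, {j})")
        if not 0.0 <= self.coupling <= 1.0:
            raise InputError(f"coupling must be in [0, 1], got {self.coupling}")


def generate_alignment(n_seqs: int, n_cols: int, background=None,
                       couplings: Sequence[CouplingSpec] = (),
                       seed: int | None = None) -> Alignment:
    """Generate a synthetic alignment; deterministic under ``seed``.

    Uncoupled columns are iid draws from ``background``; each coupled pair
    follows its :class:`CouplingSpec`. Coupled positions must be distinct
    across specs and within 1..n_cols.
    """
    if n_seqs < 2:
        raise InputError(f"an alignment needs >= 2 sequences, got {n_seqs}")
    if n_cols < 1:
        raise InputError(f"need >= 1 column, got {n_cols}")
    used: set[int] = set()
    for spec in couplings:
        for pos in spec.pair:
            if not 1 <= pos <= n_cols:
                raise InputError(f"coupled position {pos} out of range 1..{n_cols}")
            if pos in used:
                raise InputError(f"position {pos} appears in more than one coupled pair")
            used.add(pos)

    symbols, probs = _normalize_background(background)
    codes_of = np.asarray([encode_symbol(s) for s in symbols], dtype=np.uint8)
    rng = np.random.default_rng(seed)

    # support-index draws for every column, converted to alphabet codes below
    idx = rng.choice(len(symbols), size=(n_seqs, n_cols), p=probs)
    out = codes_of[idx]

    for spec in couplings:
        i, j = spec.pair
        sym_s, prob_s = _normalize_background(spec.background or background)
        codes_s = np.asarray([encode_symbol(s) for s in sym_s], dtype=np.uint8)
        f = _bijection(len(sym_s))
        src = rng.choice(len(sym_s), size=n_seqs, p=prob_s)
        indep = rng.choice(len(sym_s), size=n_seqs, p=prob_s)
        linked = rng.random(n_seqs) < spec.coupling
        dst = np.where(linked, f[src], indep)
        out[:, i - 1] = codes_s[src]
        out[:, j - 1] = codes_s[dst]

    ids = [f"seq{k + 1}" for k in range(n_seqs)]
    return Alignment(ids=ids, codes=out)


def expected_mi(spec: CouplingSpec, background=None, base: float = 2.0) -> float:
    """Population MI of a coupled pair, by exact summation of the model's joint table.

    The joint distribution is ``p(x, y) = c p(x) [y = f(x)] + (1-c) p(x) p(y)``
    with f the fixed cyclic-shift bijection; MI is the Kullback-Leibler form
    summed over the finite support.
    """
    symbols, p = _normalize_background(spec.background or background)
    k = len(symbols)
    c = spec.coupling
    f = _bijection(k)
    joint = (1.0 - c) * np.outer(p, p)
    joint[np.arange(k), f] += c * p
    px = joint.sum(axis=1)
    py = joint.sum(axis=0)
    nz = joint > 0
    ratio = joint[nz] / np.outer(px, py)[nz]
    return float((joint[nz] * np.log(ratio)).sum() / math.log(base))
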