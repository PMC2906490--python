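"""Value-range filtering and data/weight matrix combination.

Two-stage filtering mirrors typical exploratory workflows on co-evolution
matrices: first a minimum/maximum window on the mutual information, then the
same on the Z-score. Both bounds are inclusive, so exact threshold hits
survive. The Z matrix can additionally act as a weight: either multiplied
elementwise into the data matrix (joint image) or mapped through a linear
ramp to [0, 1] saturation weights that modulate color intensity in rendering.

Filtering always produces a boolean mask and never mutates values; sorting,
rendering and export all consume the mask.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InputError
from .msa_io import write_matrix_triples
from .null_model import ZMatrix


@dataclass
class FilterSpec:
    """Inclusive value windows on MI (bits) and Z (dimensionless); unbounded by default."""

    mi_min: float = -math.inf
    mi_max: float = math.inf
    z_min: float = -math.inf
    z_max: float = math.inf

    def __post_init__(self):
        if self.mi_min > self.mi_max:
            raise InputError(f"mi_min {self.mi_min} > mi_max {self.mi_max}")
        if self.z_min > self.z_max:
            raise InputError(f"z_min {self.z_min} > z_max {self.z_max}")

    @property
    def has_z_bounds(self) -> bool:
        return self.z_min > -math.inf or self.z_max < math.inf


def _z_values(z) -> np.ndarray:
    return z.values if isinstance(z, ZMatrix) else np.asarray(z, dtype=float)


def apply_filter(mi: np.ndarray, z, spec: FilterSpec) -> np.ndarray:
    """Boolean mask of cells inside the MI window and (if bounded) the Z window.

    Undefined (NaN) cells fail any bound applied to them, so pairs with a
    degenerate null never pass a Z-bounded filter.
    """
    mi = np.asarray(mi, dtype=float)
    with np.errstate(invalid="ignore"):
        mask = (mi >= spec.mi_min) & (mi <= spec.mi_max)
    if spec.has_z_bounds:
        if z is None:
            raise InputError("Z bounds set but no Z matrix supplied")
        zv = _z_values(z)
        if zv.shape != mi.shape:
            raise InputError(f"Z shape {zv.shape} does not match MI shape {mi.shape}")
        with np.errstate(invalid="ignore"):
            mask &= (zv >= spec.z_min) & (zv <= spec.z_max)
    return mask


def combine_multiply(data: np.ndarray, weight: np.ndarray) -> np.ndarray:
    """Elementwise product; cells undefined in either operand stay undefined."""
    data = np.asarray(data, dtype=float)
    weight = _z_values(weight)
    if data.shape != weight.shape:
        raise InputError(f"shape mismatch: {data.shape} vs {weight.shape}")
    return data * weight


def saturation_weights(z, z_lo: float, z_hi: float) -> np.ndarray:
    """Linear ramp of Z to [0, 1] saturation weights.

    Z <= z_lo maps to 0, Z >= z_hi to 1, linear in between; undefined Z
    yields 0 (a degenerate null carries no significance weight).
    """
    if z_lo >= z_hi:
        raise InputError(f"saturation bounds require z_lo < z_hi, got {z_lo} >= {z_hi}")
    zv = _z_values(z)
    w = np.clip((zv - z_lo) / (z_hi - z_lo), 0.0, 1.0)
    return np.nan_to_num(w, nan=0.0)


def export_selection(m: np.ndarray, mask: np.ndarray, path) -> None:
    """Write exactly the mask-true cells as a triple-format ASCII file.

    Labels are original 1-based matrix positions; an all-false mask yields a
    header-only file.
    """
    m = np.asarray(m, dtype=float)
    mask = np.asarray(mask, dtype=bool)
    if mask.shape != m.shape:
        raise InputError(f"mask shape {mask.shape} does not match matrix {m.shape}")
    write_matrix_triples(m, path, mask=mask, header="row column value")
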