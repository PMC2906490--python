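"""Color-mapped matrix images and value histograms; lossless PNG export.

Each matrix cell becomes a ``cell_px`` x ``cell_px`` block of one color
(with ``cell_px=1``, one pixel per relationship), so even large matrices
render compactly. Masked or filtered-out cells are painted in the scale's
background color; an optional saturation weight matrix in [0, 1] blends each
cell's color linearly toward the background (weight 0 = background, 1 = full
color). Rendering is fully deterministic: the same matrix, scale and options
produce bit-identical PNG bytes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable

import numpy as np
from matplotlib import colormaps as _mpl_colormaps
from PIL import Image

from .errors import InputError

#: Background for masked cells: a light neutral grey.
DEFAULT_BACKGROUND = (0.85, 0.85, 0.85)


@dataclass
class ColorScale:
    """A named continuous mapping from normalized values in [0, 1] to RGB."""

    name: str
    mapping: Callable[[np.ndarray], np.ndarray] = field(repr=False)
    background: tuple[float, float, float] = DEFAULT_BACKGROUND

    @classmethod
    def from_matplotlib(cls, name: str, mpl_name: str,
                        background=DEFAULT_BACKGROUND) -> "ColorScale":
        cmap = _mpl_colormaps[mpl_name]
        return cls(name=name, mapping=lambda v: np.asarray(cmap(v))[..., :3],
                   background=background)


def _builtin_scales() -> dict[str, ColorScale]:
    return {
        # sequential single-hue scale for MI magnitudes
        "blues": ColorScale.from_matplotlib("blues", "Blues"),
        # diverging scale, midpoint for Z = 0 under symmetric fixed-range
        "rdbu": ColorScale.from_matplotlib("rdbu", "RdBu_r"),
        "viridis": ColorScale.from_matplotlib("viridis", "viridis"),
        "greys": ColorScale.from_matplotlib("greys", "Greys"),
    }


COLOR_SCALES = _builtin_scales()


def get_color_scale(name: str) -> ColorScale:
    try:
        return COLOR_SCALES[name.lower()]
    except KeyError:
        raise InputError(
            f"unknown color scale '{name}'; available: {sorted(COLOR_SCALES)}"
        ) from None


def normalize_values(m: np.ndarray, mode: str = "global-minmax",
                     vmin: float | None = None, vmax: float | None = None) -> np.ndarray:
    """Rescale matrix values to [0, 1]; masked (NaN) cells stay masked.

    ``global-minmax`` maps the observed minimum to 0 and maximum to 1; a
    constant matrix maps to all 0.5. ``fixed-range`` rescales by the given
    (vmin, vmax) window and clips to [0, 1].
    """
    m = np.asarray(m, dtype=float)
    finite = np.isfinite(m)
    if not finite.any():
        raise InputError("cannot normalize an all-masked matrix")
    out = np.full(m.shape, np.nan)
    if mode == "global-minmax":
        lo, hi = m[finite].min(), m[finite].max()
        if hi == lo:
            out[finite] = 0.5
        else:
            out[finite] = (m[finite] - lo) / (hi - lo)
    elif mode == "fixed-range":
        if vmin is None or vmax is None or not vmin < vmax:
            raise InputError("fixed-range normalization needs vmin < vmax")
        out[finite] = np.clip((m[finite] - vmin) / (vmax - vmin), 0.0, 1.0)
    else:
        raise InputError(f"unknown normalization mode '{mode}'")
    return out


def render_matrix(m: np.ndarray, scale: ColorScale, mask: np.ndarray | None = None,
                  sat: np.ndarray | None = None, cell_px: int = 1) -> np.ndarray:
    """Render a normalized matrix as an RGB uint8 image array.

    ``m`` holds normalized values in [0, 1] (NaN = masked). ``mask``, if
    given, restricts the shown cells (True = show). ``sat`` blends shown
    cells toward the background color by its [0, 1] weight.
    """
    m = np.asarray(m, dtype=float)
    if m.ndim != 2:
        raise InputError("image rendering requires a 2-D matrix")
    if int(cell_px) != cell_px or cell_px < 1:
        raise InputError(f"cell_px must be an integer >= 1, got {cell_px}")
    cell_px = int(cell_px)

    shown = np.isfinite(m)
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != m.shape:
            raise InputError(f"mask shape {mask.shape} does not match {m.shape}")
        shown &= mask

    bg = np.asarray(scale.background, dtype=float)
    img = np.broadcast_to(bg, m.shape + (3,)).copy()
    if shown.any():
        colors = scale.mapping(np.nan_to_num(m, nan=0.0))
        if sat is not None:
            sat = np.asarray(sat, dtype=float)
            if sat.shape != m.shape:
                raise InputError(f"saturation shape {sat.shape} does not match {m.shape}")
            w = np.clip(np.nan_to_num(sat, nan=0.0), 0.0, 1.0)[..., None]
            colors = bg + w * (colors - bg)
        img[shown] = colors[shown]

    img = np.repeat(np.repeat(img, cell_px, axis=0), cell_px, axis=1)
    return np.round(img * 255.0).astype(np.uint8)


def export_png(img: np.ndarray, path, force: bool = False) -> None:
    """Write an RGB image array as lossless PNG; refuse to overwrite without force."""
    path = Path(path)
    if path.exists() and not force:
        raise FileExistsError(f"{path} exists; pass force=True to overwrite")
    Image.fromarray(np.asarray(img, dtype=np.uint8), mode="RGB").save(path, format="PNG")


def load_png(path) -> np.ndarray:
    """Decode a PNG back into an RGB uint8 array (round-trip check helper)."""
    return np.asarray(Image.open(path).convert("RGB"))


def value_histogram(m: np.ndarray, n_bins: int, mask: np.ndarray | None = None,
                    unique_pairs: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Equal-width histogram (edges, counts) of the unmasked cell values.

    ``unique_pairs=True`` counts only cells with row <= column of a square
    matrix, the natural accounting for symmetric matrices where every pair is
    stored twice. Counts always sum to the number of cells histogrammed.
    """
    m = np.asarray(m, dtype=float)
    if n_bins < 1:
        raise InputError(f"n_bins must be >= 1, got {n_bins}")
    shown = np.isfinite(m)
    if mask is not None:
        shown &= np.asarray(mask, dtype=bool)
    if unique_pairs:
        if m.ndim != 2 or m.shape[0] != m.shape[1]:
            raise InputError("unique-pairs counting requires a square matrix")
        shown &= np.triu(np.ones(m.shape, dtype=bool))
    values = m[shown]
    if values.size == 0:
        raise InputError("no unmasked cells to histogram")
    counts, edges = np.histogram(values, bins=n_bins)
    return edges, counts
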