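"""Analytic receptive-field (RF) arithmetic for strided convolution cascades.

For a cascade of convolutions with kernel ``k``, stride ``s`` and padding
``p``, every unit of layer ``l`` depends on a square region of the input
image.  Three numbers per layer describe the geometry completely:

* ``rf``    — side of that square in input pixels,
* ``jump``  — input-pixel distance between the RFs of adjacent units,
* ``start`` — input-pixel coordinate of the RF centre of unit (0, 0).

The recursion (input layer: rf=1, jump=1, start=0) is::

    rf_l    = rf_{l-1} + (k_l - 1) * jump_{l-1}
    jump_l  = jump_{l-1} * s_l
    start_l = start_{l-1} + ((k_l - 1) / 2 - p_l) * jump_{l-1}

On top of it this module maps units to image rectangles, selects units whose
RF is fully contained in a visual-field quadrant (removing border units whose
RF crosses the quadrant boundary), classifies layers into the three analysis
sections (spatial encoder / latent / spatial decoder), converts degrees of
visual angle to pixels, and extracts maximum-activation image patches.

All rectangles are 0-based half-open ``(row0, row1, col0, col1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "LayerGeom",
    "RFSpec",
    "QuadrantRegion",
    "rf_recursion",
    "unit_to_patch",
    "quadrant_units",
    "decoder_quadrant_units",
    "classify_sections",
    "deg_to_px",
    "top_activation_patches",
    "lower_right_quadrant",
    "lower_left_quadrant",
]


@dataclass(frozen=True)
class LayerGeom:
    """RF geometry of one layer."""

    name: str
    rf: int
    jump: int
    start: float
    grid: tuple[int, int]  # (rows, cols) of the layer's unit grid


@dataclass
class RFSpec:
    """Per-layer RF table for a convolution cascade (depth 0 = input)."""

    layers: list[LayerGeom]

    def __getitem__(self, name_or_index) -> LayerGeom:
        if isinstance(name_or_index, int):
            return self.layers[name_or_index]
        for lg in self.layers:
            if lg.name == name_or_index:
                return lg
        raise KeyError(f"no layer named {name_or_index!r}; have {[l.name for l in self.layers]}")

    def names(self) -> list[str]:
        return [lg.name for lg in self.layers]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(l.name, l.rf, l.jump, l.start, l.grid[0], l.grid[1]) for l in self.layers],
            columns=["layer", "rf", "jump", "start", "grid_rows", "grid_cols"],
        )


@dataclass(frozen=True)
class QuadrantRegion:
    """Pixel rectangle of one image quadrant (0-based, half-open)."""

    row0: int
    row1: int
    col0: int
    col1: int
    label: str = ""

    def as_tuple(self) -> tuple[int, int, int, int]:
        return (self.row0, self.row1, self.col0, self.col1)


def lower_right_quadrant(image_size: int, label: str = "occluded") -> QuadrantRegion:
    h = image_size // 2
    return QuadrantRegion(h, image_size, h, image_size, label)


def lower_left_quadrant(image_size: int, label: str = "nonoccluded") -> QuadrantRegion:
    h = image_size // 2
    return QuadrantRegion(h, image_size, 0, h, label)


def rf_recursion(layer_configs: Sequence[tuple], input_size: int,
                 names: Sequence[str] | None = None) -> RFSpec:
    """Run the RF recursion over an ordered cascade of conv layers.

    Parameters
    ----------
    layer_configs : sequence of (kernel, stride, padding) triples, input->deep.
    input_size : side of the (square) input image in pixels.
    names : optional layer names; defaults to ``layer_1..layer_L``.
    """
    rf, jump, start, size = 1, 1, 0.0, input_size
    layers = [LayerGeom("input", rf, jump, start, (size, size))]
    for i, (k, s, p) in enumerate(layer_configs):
        if k < 1 or s < 1:
            raise ValueError(f"layer {i + 1}: kernel and stride must be >= 1, got k={k} s={s}")
        rf = rf + (k - 1) * jump
        start = start + ((k - 1) / 2 - p) * jump
        jump = jump * s
        size = (size + 2 * p - k) // s + 1
        name = names[i] if names is not None else f"layer_{i + 1}"
        layers.append(LayerGeom(name, rf, jump, start, (size, size)))
    return RFSpec(layers)


def _rf_rect(geom: LayerGeom, pos: tuple[int, int]) -> tuple[int, int, int, int]:
    """Unclipped discrete RF support of a unit, rounded outward."""
    r = geom.rf
    cr = geom.start + pos[0] * geom.jump
    cc = geom.start + pos[1] * geom.jump
    r0 = int(np.floor(cr - (r - 1) / 2))
    r1 = int(np.ceil(cr + (r - 1) / 2)) + 1
    c0 = int(np.floor(cc - (r - 1) / 2))
    c1 = int(np.ceil(cc + (r - 1) / 2)) + 1
    return (r0, r1, c0, c1)


def unit_to_patch(rf_spec: RFSpec, layer: str | int, pos: tuple[int, int],
                  image_size: int) -> tuple[int, int, int, int]:
    """Image rectangle on which the unit at grid position ``pos`` depends.

    The rectangle is the unit's discrete RF support clipped to image bounds,
    so corner units whose formal RF extends into the padding get a smaller
    patch (matching numerical input-sensitivity support).
    """
    geom = rf_spec[layer]
    rows, cols = geom.grid
    if not (0 <= pos[0] < rows and 0 <= pos[1] < cols):
        raise IndexError(f"unit {pos} outside {geom.name} grid {geom.grid}")
    r0, r1, c0, c1 = _rf_rect(geom, pos)
    return (max(r0, 0), min(r1, image_size), max(c0, 0), min(c1, image_size))


def quadrant_units(rf_spec: RFSpec, layer: str | int,
                   region: QuadrantRegion) -> np.ndarray:
    """Units whose *full* RF rectangle lies inside ``region``.

    Border units whose RF crosses the quadrant boundary (or the image border's
    padding) are excluded.  Returns an (n, 2) int array of (row, col) grid
    positions; empty when the layer's RF no longer fits in the quadrant —
    the signal that spatiotopy is lost.
    """
    geom = rf_spec[layer]
    rows, cols = geom.grid
    half = (geom.rf - 1) / 2
    centers_r = geom.start + np.arange(rows) * geom.jump
    centers_c = geom.start + np.arange(cols) * geom.jump
    ok_r = (np.floor(centers_r - half) >= region.row0) & (np.ceil(centers_r + half) + 1 <= region.row1)
    ok_c = (np.floor(centers_c - half) >= region.col0) & (np.ceil(centers_c + half) + 1 <= region.col1)
    rr, cc = np.meshgrid(np.where(ok_r)[0], np.where(ok_c)[0], indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1).astype(int)


def decoder_quadrant_units(grid: tuple[int, int], image_size: int,
                           region: QuadrantRegion, border_cells: int = 1) -> np.ndarray:
    """Quadrant assignment for decoder layers by output-position retinotopy.

    The formal RF of a decoder unit spans the whole input (everything flows
    through the bottleneck), so spatial selection instead maps each grid cell
    linearly onto image coordinates and keeps cells whose rectangle lies
    inside the region, dropping ``border_cells`` cells adjacent to the
    quadrant boundary.
    """
    rows, cols = grid
    cell_h = image_size / rows
    cell_w = image_size / cols
    # border exclusion applies only at internal quadrant boundaries, not at
    # the outer image border
    lo_r = region.row0 + (border_cells * cell_h if region.row0 > 0 else 0)
    hi_r = region.row1 - (border_cells * cell_h if region.row1 < image_size else 0)
    lo_c = region.col0 + (border_cells * cell_w if region.col0 > 0 else 0)
    hi_c = region.col1 - (border_cells * cell_w if region.col1 < image_size else 0)
    idx_r = np.arange(rows)
    idx_c = np.arange(cols)
    ok_r = (idx_r * cell_h >= lo_r) & ((idx_r + 1) * cell_h <= hi_r)
    ok_c = (idx_c * cell_w >= lo_c) & ((idx_c + 1) * cell_w <= hi_c)
    rr, cc = np.meshgrid(np.where(ok_r)[0], np.where(ok_c)[0], indexing="ij")
    return np.stack([rr.ravel(), cc.ravel()], axis=1).astype(int)


def classify_sections(encoder_spec: RFSpec, decoder_grids: dict[str, tuple[int, int]],
                      image_size: int, min_decoder_grid: int = 16) -> dict[str, str]:
    """Label analyzed layers spatial_encoder / latent / spatial_decoder.

    Encoder layers keep a spatiotopic reading as long as some units' RFs are
    fully contained in a single lower quadrant; once the RF outgrows the
    quadrant the layer only carries context (latent).  Decoder layers regain
    retinotopy by output position once their grid is at least
    ``min_decoder_grid`` on a side.
    """
    region = lower_right_quadrant(image_size)
    labels: dict[str, str] = {}
    spatial_prefix = True
    for geom in encoder_spec.layers[1:]:  # skip the input pseudo-layer
        nonempty = len(quadrant_units(encoder_spec, geom.name, region)) > 0
        if spatial_prefix and nonempty:
            labels[geom.name] = "spatial_encoder"
        else:
            spatial_prefix = False
            labels[geom.name] = "latent"
    for name, grid in decoder_grids.items():
        labels[name] = "spatial_decoder" if min(grid) >= min_decoder_grid else "latent"
    return labels


def deg_to_px(degrees: float | np.ndarray, span_degrees: float, span_pixels: int):
    """Linear degrees-of-visual-angle to pixel conversion along one axis."""
    if span_degrees <= 0:
        raise ValueError(f"span_degrees must be positive, got {span_degrees}")
    return np.asarray(degrees, dtype=float) * span_pixels / span_degrees


def top_activation_patches(activations: np.ndarray, rf_spec: RFSpec, layer: str | int,
                           channel: int, k: int = 5, image_size: int | None = None,
                           image_ids: Sequence | None = None) -> list[dict]:
    """The ``k`` largest unit activations of one channel over an image set.

    ``activations`` is (n_images, rows, cols, channels) for ``layer``.  Ties
    are broken by (image index, row, col) ascending.  Each hit is mapped to
    its RF rectangle via :func:`unit_to_patch`.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    acts = activations[..., channel]
    n, rows, cols = acts.shape
    if k > acts.size:
        raise ValueError(f"k={k} exceeds total unit count {acts.size}")
    flat = acts.ravel()
    img, row, col = np.unravel_index(np.arange(flat.size), (n, rows, cols))
    order = np.lexsort((col, row, img, -flat))[:k]
    geom = rf_spec[layer]
    size = image_size if image_size is not None else int(geom.start + (geom.grid[0] - 1) * geom.jump + geom.rf)
    out = []
    for idx in order:
        pos = (int(row[idx]), int(col[idx]))
        out.append({
            "image_id": image_ids[img[idx]] if image_ids is not None else int(img[idx]),
            "unit": pos,
            "value": float(flat[idx]),
            "rect": unit_to_patch(rf_spec, layer, pos, size),
        })
    return out
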