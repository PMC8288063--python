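"""Quadrant-restricted activation vectors per analyzed layer.

Bridges the network and the RSA: for each analyzed layer the activation map
is reduced to the units assigned to one image quadrant —

* ``spatial_encoder`` layers keep the units whose receptive field lies fully
  inside the quadrant (border units removed);
* ``spatial_decoder`` layers keep grid cells mapped into the quadrant by
  output-position retinotopy (border cells removed);
* ``latent`` layers have no spatial reading, so the full activation vector
  stands for both quadrants.

The flattened (units x channels) vectors feed the PCA reduction.
"""

from __future__ import annotations

from typing import Iterator, Sequence

import numpy as np

from . import network as nw
from . import rf_geometry as rfg

__all__ = ["layer_unit_index", "quadrant_features", "activation_stream"]


def layer_unit_index(config: nw.ArchitectureConfig, quadrant: str,
                     min_decoder_grid: int = 16) -> dict[str, np.ndarray | None]:
    """Per analyzed layer: (n, 2) unit positions for the quadrant, or ``None``
    for latent layers (full vector)."""
    size = config.input_size
    region = (rfg.lower_right_quadrant(size) if quadrant == "occluded"
              else rfg.lower_left_quadrant(size))
    spec = nw.encoder_rf_spec(config)
    grids = nw.decoder_grids(config)
    index: dict[str, np.ndarray | None] = {}
    for name, section in nw.analyzed_layers(config, min_decoder_grid):
        if section == "spatial_encoder":
            index[name] = rfg.quadrant_units(spec, name, region)
        elif section == "spatial_decoder":
            g = grids[name]
            cell_region = rfg.QuadrantRegion(*region.as_tuple(), region.label)
            index[name] = rfg.decoder_quadrant_units(g, size, cell_region)
        else:
            index[name] = None
    return index


def _restrict(acts: np.ndarray, units: np.ndarray | None) -> np.ndarray:
    """(n, h, w, c) -> (n, d) flattened quadrant restriction."""
    if units is None:
        return acts.reshape(len(acts), -1)
    sel = acts[:, units[:, 0], units[:, 1], :]
    return sel.reshape(len(acts), -1)


def quadrant_features(net: nw.EncoderDecoder, images: np.ndarray, quadrant: str,
                      layers: Sequence[str] | None = None,
                      batch_size: int = 8) -> dict[str, np.ndarray]:
    """Flattened quadrant-restricted activations per analyzed layer."""
    index = layer_unit_index(net.config, quadrant)
    names = list(layers) if layers is not None else list(index)
    acts = nw.forward_collect(net, images, names, batch_size=batch_size)
    return {n: _restrict(acts[n], index[n]) for n in names}


def vgg_rf_spec(topology: Sequence[dict], image_size: int) -> rfg.RFSpec:
    """RF table over the baseline topology (3x3 convs and 2x2 pools)."""
    cfgs, names = [], []
    for entry in topology:
        if entry["kind"] == "conv":
            cfgs.append((entry.get("kernel", 3), entry.get("stride", 1), entry.get("padding", 1)))
        else:
            cfgs.append((2, 2, 0))
        names.append(entry["name"])
    return rfg.rf_recursion(cfgs, image_size, names=names)


def vgg_quadrant_features(vgg_net: list, topology: Sequence[dict], images: np.ndarray,
                          quadrant: str, image_size: int,
                          batch_size: int = 4) -> dict[str, np.ndarray]:
    """Quadrant-restricted activations of the baseline's 5 analyzed conv
    layers (units with full RF containment; layers whose RF outgrows the
    quadrant fall back to the full vector, mirroring the latent treatment)."""
    names = nw.vgg_analysis_layers(topology)
    spec = vgg_rf_spec(topology, image_size)
    region = (rfg.lower_right_quadrant(image_size) if quadrant == "occluded"
              else rfg.lower_left_quadrant(image_size))
    acts = nw.vgg_forward_collect(vgg_net, images, names, batch_size=batch_size)
    out = {}
    for n in names:
        units = rfg.quadrant_units(spec, n, region)
        out[n] = _restrict(acts[n], units if len(units) else None)
    return out


def activation_stream(net: nw.EncoderDecoder, layer: str, quadrant: str,
                      image_batches: Iterator[np.ndarray]) -> Iterator[np.ndarray]:
    """Stream flattened quadrant-restricted activations of one layer, batch by
    batch, for incremental PCA fitting."""
    units = layer_unit_index(net.config, quadrant)[layer]
    for batch in image_batches:
        acts = nw.forward_collect(net, batch, [layer], batch_size=len(batch))[layer]
        yield _restrict(acts, units)
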