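"""Receptive-field arithmetic of the encoder and the three analysis sections.

Each stride-2 convolution grows the units' receptive field (4 px after the
first layer, 22 px after the third); once the RF outgrows a 128-px image
quadrant (layer 6 onward), units can no longer be assigned to a quadrant and
the layer only carries context — the basis of the spatial-encoder / latent /
spatial-decoder sectioning.
"""

from visfill import network as nw
from visfill import rf_geometry as rfg

arch = nw.default_architecture(256)
spec = nw.encoder_rf_spec(arch)
print(spec.to_frame().to_string(index=False))

region = rfg.lower_right_quadrant(256)
print("\nunits whose RF fits inside the lower-right quadrant:")
for geom in spec.layers[1:]:
    units = rfg.quadrant_units(spec, geom.name, region)
    print(f"  {geom.name}: rf={geom.rf:>3} px -> {len(units)} units")

print("\nanalyzed layers and sections (15 total):")
for name, section in nw.analyzed_layers(arch):
    print(f"  {name:<10} {section}")

px = rfg.deg_to_px(2.0, span_degrees=19.5, span_pixels=256)
print(f"\n2.0 deg of visual angle = {px:.1f} px at the 19.5-deg/256-px scale")
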