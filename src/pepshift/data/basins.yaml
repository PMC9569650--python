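# pepshift backbone-basin parameters, version 1
#
# Ramachandran basins shared by the synthetic ensemble generator and the
# built-in toy chemical-shift predictor, so that generation and prediction
# are mutually consistent by construction.
#
# centers/widths: (phi, psi) in degrees; widths are wrapped-normal sigmas.
# offsets: secondary-shift offsets (ppm) added to the random-coil value by
# the toy predictor for a residue whose (phi, psi) falls in the basin.
basins:
  helix:
    center: [-63.0, -42.0]
    width: [10.0, 10.0]
    offsets: {CA: 2.6, CB: -0.4, HA: -0.35, H: -0.15, N: -1.5}
  strand:
    center: [-120.0, 130.0]
    width: [15.0, 15.0]
    offsets: {CA: -1.4, CB: 1.0, HA: 0.35, H: 0.15, N: 1.5}
  coil:
    center: [-75.0, 150.0]
    width: [25.0, 25.0]
    offsets: {CA: 0.0, CB: 0.0, HA: 0.0, H: 0.0, N: 0.0}
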