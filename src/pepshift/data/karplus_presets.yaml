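# pepshift Karplus coefficient presets for 3J(HN-HA), version 1
# J(phi) = A*cos^2(phi - theta0) + B*cos(phi - theta0) + C, Hz, degrees.
# theta0 = +60 deg is the standard H-N-CA-HA phase for the backbone phi.
presets:
  vuister_bax_1993: {A: 6.51, B: -1.76, C: 1.60, theta0: 60.0}
  hu_bax_1997: {A: 7.09, B: -1.42, C: 1.55, theta0: 60.0}
default: hu_bax_1997
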