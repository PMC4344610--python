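# Default conformer taxonomy of a 1->x glycosidic linkage on the phi/psi
# torus: phi pinned near +30 by the exo-anomeric effect, psi selecting
# between state I (+40), state II (0) and the inverted state III (+/-180).
states:
  - {label: I, phi_center: 30.0, psi_center: 40.0, radius: 35.0}
  - {label: II, phi_center: 30.0, psi_center: 0.0, radius: 35.0}
  - {label: III, phi_center: 30.0, psi_center: 180.0, radius: 35.0}
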