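# Default glycosidic-linkage torsion definitions (proton-based convention):
#   phi = H1-C1-O-Cx,  psi = C1-O-Cx-Hx   for a 1->x linkage.
name: "Fuc(1->3)GlA"
phi_atoms: [H1, C1, O, C3]
psi_atoms: [C1, O, C3, H3]
aglycon_position: 3
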