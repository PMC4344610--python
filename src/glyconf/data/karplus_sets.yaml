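# Named Karplus parameterizations for trans-glycosidic 3J(C-O-C-H):
#   J(theta) = A*cos^2(theta) + B*cos(theta) + C   [Hz]
# tvaroska1989 is the standard C-O-C-H parameterization
# (Tvaroska, Hricovini & Petrakova, Carbohydr. Res. 189 (1989) 359).
tvaroska1989:
  A: 5.7
  B: -0.6
  C: 0.5
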