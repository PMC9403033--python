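# Van der Waals radii by element (Angstrom). Bondi-style values for the
# elements found in protein crystal structures; hydrogens are listed for
# completeness but ignored by the parser.
C: 1.70
N: 1.55
O: 1.52
S: 1.80
SE: 1.90
P: 1.80
H: 1.20
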