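# Resonant functional groups whose integer formal charges are redistributed
# over symmetry-equivalent heteroatoms before partial charges are computed.
# mode "terminal": the summed integer formal charge of all equivalent terminal
#   atoms (of the listed numeric types) bonded to the same center is shared
#   equally among them.
# mode "pair":     a charge of the listed amount is placed on each atom of the
#   listed type (resonance-equivalent positions, e.g. amidinium nitrogens).
# mode "ring":     the summed charge of all same-type atoms in one aromatic
#   ring is shared equally among them (e.g. tetrazolate).
# columns: name mode member_types value
carboxylate      terminal 32  -
thiocarboxylate  terminal 72  -
amidinium        pair     55  0.5
guanidinium      pair     56  0.333333333333
imidazolium      pair     81  0.5
aromatic_azolate ring     76  -
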