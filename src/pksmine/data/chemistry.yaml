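# Monoisotopic element masses (CODATA/AME-sourced), adduct conventions and the
# starter-unit library for beta-amino-acid primed macrolactams.
element_masses:
  C: 12.0
  H: 1.00782503207
  N: 14.0030740048
  O: 15.9949146196
  Na: 22.9897692820
  S: 31.97207100
  P: 30.97376163

# Adducts add NEUTRAL atom masses (electron mass neglected), reproducing the
# printed "calcd" convention of natural-product papers rather than the
# physically exact protonated-species m/z (which would be ~0.0005 Da lower).
adducts:
  "[M+H]+": {H: 1}
  "[M+Na]+": {Na: 1}
  "M": {}

# Net formula change removed by amide deprotection (glycyl protecting amide:
# +Gly -H2O while protected).
protecting_group_delta:
  C: 2
  H: 3
  N: 1
  O: 1

# ring_atoms counts atoms contributed to the macrolactam ring INCLUDING the
# amide nitrogen; methyl_positions index ring carbons from the starter
# carboxyl carbon (position 1).
starters:
  3-amino-2-methylpropionate:
    ring_atoms: 4
    methyl_positions: [2]
    amine_protected: true
  3-methylaspartate:
    # precursor of 3-amino-2-methylpropionate; declarative entry with the
    # post-decarboxylation ring contribution
    ring_atoms: 4
    methyl_positions: [2]
    amine_protected: true
  3-aminobutyrate:
    ring_atoms: 4
    methyl_positions: [3]
    amine_protected: false
  3-aminopropionate:
    ring_atoms: 4
    methyl_positions: []
    amine_protected: false
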