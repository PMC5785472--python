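# Product specification for sceliphrolactam, the 26-membered polyene
# macrolactam (C28H35NO6) primed with a 3-amino-2-methylpropionate starter.
#
# The per-extension beta-state sequence is figure-derived (the biosynthetic
# scheme is drawn, not tabulated) and constrained by the molecular formula:
# 11 extensions resolve to 8 enoyl + 2 ketone + 1 hydroxyl states with methyl
# branches at extensions 3 and 9.  The cis (Z) double bond between C-14 and
# C-15 is a spectroscopic assignment declared as a geometry override — no
# domain rule predicts it.  Hydroxylations at C-10/C-12 are cytochrome P450
# tailoring; the amide deprotection frees the starter amine after assembly.
name: sceliphrolactam
formula: {C: 28, H: 35, N: 1, O: 6}
ring_size: 26
starter: 3-amino-2-methylpropionate
branch_positions: [3, 9]
target_units:
  - {position: 1, alpha: H, beta: enoyl}
  - {position: 2, alpha: H, beta: enoyl}
  - {position: 3, alpha: CH3, beta: enoyl}
  - {position: 4, alpha: H, beta: enoyl}
  - {position: 5, alpha: H, beta: enoyl, geometry: Z}
  - {position: 6, alpha: H, beta: ketone}
  - {position: 7, alpha: H, beta: hydroxyl, stereo: R}
  - {position: 8, alpha: H, beta: enoyl}
  - {position: 9, alpha: CH3, beta: ketone}
  - {position: 10, alpha: H, beta: enoyl}
  - {position: 11, alpha: H, beta: enoyl}
position_annotations:
  C-10: 7
  C-11: 7
  C-12: 6
  C-14: 5
  C-15: 5
  C-26: 9
  C-27: 3
tailoring:
  - {kind: hydroxylation, site: C-10, agent: sceD}
  - {kind: hydroxylation, site: C-12, agent: sceE}
  - {kind: amide_deprotection, agent: sceF}
geometry_overrides: {5: Z}
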