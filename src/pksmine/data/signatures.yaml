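# Signature tables for motif-anchored domain scanning and classification.
#
# The AT specificity window (YASH = methylmalonyl-CoA, HAFH = malonyl-CoA) and
# the KR typing rules (B-type [LV]D[DN] motif; A-type tryptophan criterion,
# which is extrapolated from the KR-typing literature rather than stated
# alongside the B rule) are editable here so alternative residue sets can be
# swapped in without code changes.
domains:
  KS:
    anchor: "EPIAI[VA]G"
    lead: 4
    width: 70
    catalytic:
      KS_cys: "TACSSS"
  AT:
    anchor: "GQG[AS]Q"
    lead: 4
    width: 80
    catalytic:
      AT_ser: "GHS[A-Z]G"
  DH:
    anchor: "H[A-Z]{3}G[A-Z]{4}P"
    lead: 4
    width: 60
    catalytic:
      DH_his: "H[A-Z]{3}G[A-Z]{4}P"
  ER:
    anchor: "GGVG[A-Z]A"
    lead: 4
    width: 60
    catalytic: {}
  KR:
    anchor: "GG[TS]G[A-Z]LG"
    lead: 4
    width: 70
    catalytic:
      KR_tyr: "Y[A-Z]{3}N"
  ACP:
    anchor: "G[A-Z]DSL"
    lead: 4
    width: 40
    catalytic:
      ACP_ser: "DSL"
  TE:
    anchor: "G[WF]S[A-Z]G"
    lead: 4
    width: 50
    catalytic:
      TE_ser: "G[WF]S[A-Z]G"

at:
  active_site: "GHS[A-Z]G"
  # residues from the start of the GHSxG match to the start of the
  # 4-residue specificity window
  window_offset: 14
  window_len: 4
  patterns:
    methylmalonyl: "YASH"
    malonyl: "HAFH"

kr:
  min_len: 20
  # window searched for the type motif, in residues after the end of the
  # Rossmann-fold anchor match
  type_window: [8, 20]
  b_motif: "[LV]D[DN]"
  a_motif: "W"          # extrapolated A-type criterion; flagged in reports
  catalytic: "Y[A-Z]{3}N"

docking:
  min_len: 25
  score_threshold: 0.8
  hydrophobic: "ILVMF"
  # upstream C-terminal dock class -> compatible downstream N-terminal classes
  pairing:
    CC0: ["CC0"]
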