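# Default regulatory topology for the gap-gene network.
#
# Each edge carries an edge class (regulator name + role superscript) that the
# model variants map to a binding-affinity parameter (K, K1, K2 or K3).  The
# class-to-parameter assignment is defined per model variant in model_spec;
# this file only says who regulates whom and in which mode.
#
# The `Bcd^R` and `Hb^A` classes exist in the affinity tables but their target
# assignment is not fixed here; add edges with those classes below to enable
# them (they resolve to the global affinity K in every variant).
edges:
  - {regulator: Bcd, target: Hb, mode: activator, class: "Bcd^A"}
  - {regulator: Bcd, target: Kni, mode: activator, class: "Bcd^A"}
  - {regulator: Bcd, target: Gt, mode: activator, class: "Bcd^A"}
  - {regulator: Cad, target: Kni, mode: activator, class: "Cad^A"}
  - {regulator: Cad, target: Gt, mode: activator, class: "Cad^A"}
  - {regulator: Hb, target: Kr, mode: dual, class: "Hb^D"}
  - {regulator: Hb, target: Kni, mode: repressor, class: "Hb^R"}
  - {regulator: Kr, target: Gt, mode: repressor, class: "Kr^R"}
  - {regulator: Gt, target: Kr, mode: repressor, class: "Gt^R"}
  - {regulator: Kni, target: Hb, mode: repressor, class: "Kni^R"}
  - {regulator: Tll, target: Kr, mode: repressor, class: "Tll^R"}
  - {regulator: Tll, target: Kni, mode: repressor, class: "Tll^R"}
  - {regulator: Tll, target: Gt, mode: repressor, class: "Tll^R"}

# Edge added only by the D7/D8 variants (candidate activation of Kr by Bcd).
optional_edges:
  bcd_kr: {regulator: Bcd, target: Kr, mode: activator, class: "Bcd^A"}
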