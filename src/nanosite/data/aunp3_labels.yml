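# Role assignment for the PEG-linker particle naming (O12/O15 linker).
by_name:
  AU: GOLD
  S: SULFUR
  C1: ALKYL_C1
  C2: ALKYL_C2
  C3: ALKYL_C3
  C4: ALKYL_C4
  C5: ALKYL_C5
  C6: ALKYL_C6
  C7: ALKYL_C7
  HC1: OTHER
  HC2: OTHER
  HC3: OTHER
  HC4: OTHER
  HC5: OTHER
  HC6: OTHER
  HC7: OTHER
  O8: O8
  N9: N9
  HN9: OTHER
  O12: LINKER_12
  O15: LINKER_15
  N18: N18
  O19: O19
  NT1: TACN_N
  NT2: TACN_N
  NT3: TACN_N
  CT1: TACN_C
  CT2: TACN_C
  CT3: TACN_C
  ZN: ZN
  P: SUB_P
  O3: SUB_O3
  O4: SUB_O4
  O5: SUB_O5
  OW: WATER_O
  HW1: WATER_H
  HW2: WATER_H
  CL: CL
ligand_resnames: [LIG]
substrate_resnames: [HPN]
default: OTHER
masses:
  LINKER_12: 15.999
  LINKER_15: 15.999
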