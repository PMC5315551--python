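nodes:
- name: L_IFG
  mni:
  - -54.0
  - 12.0
  - 18.0
- name: R_IFG
  mni:
  - 54.0
  - 12.0
  - 18.0
- name: L_DLPFC
  mni:
  - -37.0
  - 27.0
  - 39.0
- name: R_DLPFC
  mni:
  - 37.0
  - 27.0
  - 39.0
- name: preSMA_dACC
  mni:
  - 0.0
  - -6.0
  - 56.0
- name: BG
  mni: null
input_nodes:
- L_IFG
- R_IFG
- L_DLPFC
- R_DLPFC
connections:
- source: L_IFG
  target: L_DLPFC
  kind: forward
- source: L_DLPFC
  target: L_IFG
  kind: backward
- source: R_IFG
  target: R_DLPFC
  kind: forward
- source: R_DLPFC
  target: R_IFG
  kind: backward
- source: L_DLPFC
  target: preSMA_dACC
  kind: backward
- source: R_DLPFC
  target: preSMA_dACC
  kind: backward
- source: preSMA_dACC
  target: BG
  kind: lateral
- source: BG
  target: preSMA_dACC
  kind: lateral
- source: L_IFG
  target: BG
  kind: lateral
- source: BG
  target: L_IFG
  kind: lateral
- source: R_IFG
  target: BG
  kind: lateral
- source: BG
  target: R_IFG
  kind: lateral
- source: L_IFG
  target: R_IFG
  kind: lateral
- source: L_DLPFC
  target: R_DLPFC
  kind: lateral
models:
  IFG_afferent:
  - L_IFG->BG
  - R_IFG->BG
  IFG_efferent:
  - BG->L_IFG
  - BG->R_IFG
  IFG_both:
  - L_IFG->BG
  - R_IFG->BG
  - BG->L_IFG
  - BG->R_IFG
  preSMA_afferent:
  - preSMA_dACC->BG
  preSMA_efferent:
  - BG->preSMA_dACC
  preSMA_both:
  - preSMA_dACC->BG
  - BG->preSMA_dACC
  both_afferent:
  - L_IFG->BG
  - R_IFG->BG
  - preSMA_dACC->BG
  both_efferent:
  - BG->L_IFG
  - BG->R_IFG
  - BG->preSMA_dACC
  both_both:
  - L_IFG->BG
  - R_IFG->BG
  - BG->L_IFG
  - BG->R_IFG
  - preSMA_dACC->BG
  - BG->preSMA_dACC
families:
  IFG:
  - IFG_afferent
  - IFG_efferent
  - IFG_both
  preSMA:
  - preSMA_afferent
  - preSMA_efferent
  - preSMA_both
  both:
  - both_afferent
  - both_efferent
  - both_both
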