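mode: FULL_FACTORIAL
points:
- name: age
  kind: CONTINUOUS
  tested_values:
  - '45'
  - '60'
  - '75'
- name: pt_stage
  kind: CATEGORICAL
  tested_values:
  - T1
  - T2
  - T3
  - T4
- name: pn_stage
  kind: CATEGORICAL
  tested_values:
  - N0
  - N1
  - N2
- name: nodes_examined
  kind: CATEGORICAL
  tested_values:
  - LT10
  - GE10
- name: differentiation
  kind: CATEGORICAL
  tested_values:
  - WELL_MODERATE
  - POOR_UNDIFF
- name: vascular_invasion
  kind: CATEGORICAL
  tested_values:
  - 'false'
  - 'true'
- name: obstruction_or_perforation
  kind: CATEGORICAL
  tested_values:
  - 'false'
  - 'true'
- name: msi_status
  kind: CATEGORICAL
  tested_values:
  - MSS
  - MSI
- name: oxaliplatin_contraindicated
  kind: CATEGORICAL
  tested_values:
  - 'false'
  - 'true'
- name: serious_liver_disease
  kind: CATEGORICAL
  tested_values:
  - 'false'
  - 'true'
- name: serious_kidney_disease
  kind: CATEGORICAL
  tested_values:
  - 'false'
  - 'true'
- name: resection_margin
  kind: CATEGORICAL
  held_constant: true
  constant_value: NEGATIVE
- name: perineural_invasion
  kind: CATEGORICAL
  held_constant: true
  constant_value: 'false'
- name: functional_status
  kind: CONTINUOUS
  held_constant: true
  constant_value: '0'
guideline_point_names:
- age
- differentiation
- msi_status
- nodes_examined
- obstruction_or_perforation
- oxaliplatin_contraindicated
- pn_stage
- pt_stage
- vascular_invasion
advisor_point_names:
- age
- differentiation
- functional_status
- msi_status
- nodes_examined
- obstruction_or_perforation
- perineural_invasion
- pn_stage
- pt_stage
- resection_margin
- serious_kidney_disease
- serious_liver_disease
- vascular_invasion
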