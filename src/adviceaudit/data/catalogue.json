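[
  {
    "code": "OBSERVATION",
    "label": "Observation (no adjuvant treatment)",
    "is_chemotherapy": false
  },
  {
    "code": "CAPE_MONO",
    "label": "Capecitabine monotherapy",
    "is_chemotherapy": true
  },
  {
    "code": "FU_LV_MONO",
    "label": "5-FU/leucovorin monotherapy",
    "is_chemotherapy": true
  },
  {
    "code": "CAPOX",
    "label": "Capecitabine + oxaliplatin",
    "is_chemotherapy": true
  },
  {
    "code": "FOLFOX",
    "label": "5-FU/leucovorin + oxaliplatin",
    "is_chemotherapy": true
  },
  {
    "code": "OTHER_SYSTEMIC",
    "label": "Other systemic therapy",
    "is_chemotherapy": true
  }
]
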