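{
  "name": "dutch-adjuvant-colon",
  "root": "nodal_status",
  "nodes": {
    "nodal_status": {
      "field": "pn_stage",
      "edges": [
        {
          "values": [
            "N0"
          ],
          "target": "t_stage"
        },
        {
          "values": [
            "N1",
            "N2"
          ],
          "target": "iii_oxali"
        }
      ]
    },
    "t_stage": {
      "field": "pt_stage",
      "edges": [
        {
          "values": [
            "T1",
            "T2"
          ],
          "target": "leaf_observation"
        },
        {
          "values": [
            "T3"
          ],
          "target": "ii_nodes"
        },
        {
          "values": [
            "T4"
          ],
          "target": "ii_msi"
        }
      ]
    },
    "ii_nodes": {
      "field": "nodes_examined",
      "edges": [
        {
          "values": [
            "LT10"
          ],
          "target": "ii_msi"
        },
        {
          "values": [
            "GE10"
          ],
          "target": "ii_diff"
        }
      ]
    },
    "ii_diff": {
      "field": "differentiation",
      "edges": [
        {
          "values": [
            "POOR_UNDIFF"
          ],
          "target": "ii_msi"
        },
        {
          "values": [
            "WELL_MODERATE"
          ],
          "target": "ii_vasc"
        }
      ]
    },
    "ii_vasc": {
      "field": "vascular_invasion",
      "edges": [
        {
          "values": [
            "true"
          ],
          "target": "ii_msi"
        },
        {
          "values": [
            "false"
          ],
          "target": "ii_obstr"
        }
      ]
    },
    "ii_obstr": {
      "field": "obstruction_or_perforation",
      "edges": [
        {
          "values": [
            "true"
          ],
          "target": "ii_msi"
        },
        {
          "values": [
            "false"
          ],
          "target": "leaf_observation"
        }
      ]
    },
    "ii_msi": {
      "field": "msi_status",
      "edges": [
        {
          "values": [
            "MSI"
          ],
          "target": "leaf_observation"
        },
        {
          "values": [
            "MSS"
          ],
          "target": "ii_oxali"
        }
      ]
    },
    "ii_oxali": {
      "field": "oxaliplatin_contraindicated",
      "edges": [
        {
          "values": [
            "true"
          ],
          "target": "leaf_observation"
        },
        {
          "values": [
            "false"
          ],
          "target": "leaf_ii_consider"
        }
      ]
    },
    "iii_oxali": {
      "field": "oxaliplatin_contraindicated",
      "edges": [
        {
          "values": [
            "false"
          ],
          "target": "leaf_iii_doublet"
        },
        {
          "values": [
            "true"
          ],
          "target": "iii_msi"
        }
      ]
    },
    "iii_msi": {
      "field": "msi_status",
      "edges": [
        {
          "values": [
            "MSS"
          ],
          "target": "leaf_iii_mono"
        },
        {
          "values": [
            "MSI"
          ],
          "target": "leaf_observation"
        }
      ]
    }
  },
  "leaves": {
    "leaf_observation": {
      "OBSERVATION": "R",
      "CAPE_MONO": "NR",
      "FU_LV_MONO": "NR",
      "CAPOX": "NR",
      "FOLFOX": "NR",
      "OTHER_SYSTEMIC": "NR"
    },
    "leaf_ii_consider": {
      "OBSERVATION": "R",
      "CAPE_MONO": "NR",
      "FU_LV_MONO": "NR",
      "CAPOX": "C",
      "FOLFOX": "C",
      "OTHER_SYSTEMIC": "NR"
    },
    "leaf_iii_doublet": {
      "OBSERVATION": "NR",
      "CAPE_MONO": "NR",
      "FU_LV_MONO": "NR",
      "CAPOX": "R",
      "FOLFOX": "R",
      "OTHER_SYSTEMIC": "NR"
    },
    "leaf_iii_mono": {
      "OBSERVATION": "NR",
      "CAPE_MONO": "R",
      "FU_LV_MONO": "R",
      "CAPOX": "NR",
      "FOLFOX": "NR",
      "OTHER_SYSTEMIC": "NR"
    }
  }
}
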