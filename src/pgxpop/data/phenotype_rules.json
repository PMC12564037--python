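{
  "comment": "Diplotype-to-phenotype rule tables. mode=score_interval classifies by summed activity (intervals are (prev, max] with 'inclusive' controlling the upper edge); mode=class_pair classifies by the unordered pair of allele function classes. 'bundled' is the default table; 'cpic_strict' ships for sensitivity comparison runs.",
  "tables": {
    "bundled": {
      "CYP2D6": {
        "mode": "score_interval",
        "activity": {"*1": 1.0, "*41": 0.5, "*9": 0.25, "*10": 0.25, "*3": 0.0, "*4": 0.0, "*6": 0.0},
        "intervals": [
          {"max": 0.0, "inclusive": true, "phenotype": "PM"},
          {"max": 1.0, "inclusive": true, "phenotype": "IM"},
          {"max": 2.25, "inclusive": true, "phenotype": "NM"}
        ]
      },
      "CYP2C19": {
        "mode": "class_pair",
        "activity": {"*1": 1.0, "*2": 0.0, "*3": 0.0, "*4": 0.0, "*17": 1.5},
        "classes": {"*1": "normal", "*2": "none", "*3": "none", "*4": "none", "*17": "increased"},
        "pairs": {
          "none|none": "PM",
          "none|normal": "IM",
          "increased|none": "IM",
          "normal|normal": "NM",
          "increased|normal": "RM",
          "increased|increased": "UM"
        }
      },
      "CYP2C9": {
        "mode": "class_pair",
        "activity": {"*1": 1.0, "*2": 0.5, "*3": 0.0},
        "classes": {"*1": "normal", "*2": "reduced", "*3": "reduced"},
        "pairs": {
          "normal|normal": "NM",
          "normal|reduced": "IM",
          "reduced|reduced": "PM"
        }
      }
    },
    "cpic_strict": {
      "CYP2D6": {
        "mode": "score_interval",
        "activity": {"*1": 1.0, "*41": 0.5, "*9": 0.5, "*10": 0.25, "*3": 0.0, "*4": 0.0, "*6": 0.0},
        "intervals": [
          {"max": 0.0, "inclusive": true, "phenotype": "PM"},
          {"max": 1.25, "inclusive": false, "phenotype": "IM"},
          {"max": 2.25, "inclusive": true, "phenotype": "NM"}
        ]
      },
      "CYP2C19": {
        "mode": "class_pair",
        "activity": {"*1": 1.0, "*2": 0.0, "*3": 0.0, "*4": 0.0, "*17": 1.5},
        "classes": {"*1": "normal", "*2": "none", "*3": "none", "*4": "none", "*17": "increased"},
        "pairs": {
          "none|none": "PM",
          "none|normal": "IM",
          "increased|none": "IM",
          "normal|normal": "NM",
          "increased|normal": "RM",
          "increased|increased": "UM"
        }
      },
      "CYP2C9": {
        "mode": "score_interval",
        "activity": {"*1": 1.0, "*2": 0.5, "*3": 0.0},
        "intervals": [
          {"max": 0.5, "inclusive": true, "phenotype": "PM"},
          {"max": 1.5, "inclusive": true, "phenotype": "IM"},
          {"max": 2.0, "inclusive": true, "phenotype": "NM"}
        ]
      }
    }
  }
}
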