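{
 "$defs": {
  "GroupTests": {
   "properties": {
    "larger_vs_smaller": {
     "additionalProperties": {
      "$ref": "#/$defs/PairedCell"
     },
     "title": "Larger Vs Smaller",
     "type": "object"
    },
    "left_vs_right": {
     "additionalProperties": {
      "$ref": "#/$defs/PairedCell"
     },
     "title": "Left Vs Right",
     "type": "object"
    },
    "male_vs_female": {
     "additionalProperties": {
      "$ref": "#/$defs/UnpairedCell"
     },
     "title": "Male Vs Female",
     "type": "object"
    }
   },
   "required": [
    "male_vs_female",
    "left_vs_right",
    "larger_vs_smaller"
   ],
   "title": "GroupTests",
   "type": "object"
  },
  "NormalityCell": {
   "properties": {
    "W": {
     "title": "W",
     "type": "number"
    },
    "p": {
     "maximum": 1.0,
     "minimum": 0.0,
     "title": "P",
     "type": "number"
    }
   },
   "required": [
    "W",
    "p"
   ],
   "title": "NormalityCell",
   "type": "object"
  },
  "PairedCell": {
   "properties": {
    "degenerate": {
     "default": false,
     "title": "Degenerate",
     "type": "boolean"
    },
    "p_paired": {
     "anyOf": [
      {
       "type": "number"
      },
      {
       "type": "null"
      }
     ],
     "default": null,
     "title": "P Paired"
    },
    "p_unpaired": {
     "maximum": 1.0,
     "minimum": 0.0,
     "title": "P Unpaired",
     "type": "number"
    }
   },
   "required": [
    "p_unpaired"
   ],
   "title": "PairedCell",
   "type": "object"
  },
  "TermCell": {
   "properties": {
    "coef": {
     "title": "Coef",
     "type": "number"
    },
    "p": {
     "maximum": 1.0,
     "minimum": 0.0,
     "title": "P",
     "type": "number"
    }
   },
   "required": [
    "coef",
    "p"
   ],
   "title": "TermCell",
   "type": "object"
  },
  "UnpairedCell": {
   "properties": {
    "p_unpaired": {
     "maximum": 1.0,
     "minimum": 0.0,
     "title": "P Unpaired",
     "type": "number"
    }
   },
   "required": [
    "p_unpaired"
   ],
   "title": "UnpairedCell",
   "type": "object"
  }
 },
 "description": "Schema version 1 of the cohort statistics report.",
 "properties": {
  "correlations": {
   "additionalProperties": {
    "additionalProperties": {
     "additionalProperties": {
      "type": "number"
     },
     "type": "object"
    },
    "type": "object"
   },
   "title": "Correlations",
   "type": "object"
  },
  "gender_volume_difference_pct": {
   "title": "Gender Volume Difference Pct",
   "type": "number"
  },
  "group_tests": {
   "additionalProperties": {
    "$ref": "#/$defs/GroupTests"
   },
   "title": "Group Tests",
   "type": "object"
  },
  "n_excluded": {
   "minimum": 0,
   "title": "N Excluded",
   "type": "integer"
  },
  "n_retained": {
   "minimum": 0,
   "title": "N Retained",
   "type": "integer"
  },
  "n_screened": {
   "minimum": 0,
   "title": "N Screened",
   "type": "integer"
  },
  "normality": {
   "additionalProperties": {
    "additionalProperties": {
     "additionalProperties": {
      "$ref": "#/$defs/NormalityCell"
     },
     "type": "object"
    },
    "type": "object"
   },
   "title": "Normality",
   "type": "object"
  },
  "schema_version": {
   "title": "Schema Version",
   "type": "integer"
  },
  "volume_area_ratio": {
   "additionalProperties": {
    "type": "number"
   },
   "title": "Volume Area Ratio",
   "type": "object"
  },
  "volume_model": {
   "additionalProperties": {
    "additionalProperties": {
     "$ref": "#/$defs/TermCell"
    },
    "type": "object"
   },
   "title": "Volume Model",
   "type": "object"
  }
 },
 "required": [
  "schema_version",
  "n_screened",
  "n_retained",
  "n_excluded",
  "normality",
  "group_tests",
  "volume_model",
  "correlations",
  "gender_volume_difference_pct",
  "volume_area_ratio"
 ],
 "title": "StatsReportModel",
 "type": "object"
}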