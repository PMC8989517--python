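{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "gcrtools run report",
  "type": "object",
  "required": ["tool_version", "config", "arms"],
  "properties": {
    "tool_version": {"type": "string"},
    "config": {"type": "object"},
    "cnv_correlation": {
      "type": "object",
      "properties": {
        "per_bin": {"$ref": "#/$defs/correlation"},
        "per_chromosome": {"$ref": "#/$defs/correlation"}
      }
    },
    "common_high_cnv_bp": {"type": "integer", "minimum": 0},
    "arms": {
      "type": "object",
      "additionalProperties": {
        "type": "object",
        "required": ["n_matches", "n_cuts", "n_junctions", "stats"],
        "properties": {
          "n_matches": {"type": "integer", "minimum": 0},
          "n_cuts": {"type": "integer", "minimum": 0},
          "n_junctions": {"type": "integer", "minimum": 0},
          "junction_classes": {
            "type": "object",
            "additionalProperties": {"type": "integer"}
          },
          "cnv_profile_mean": {"type": "number"},
          "cnv_profile_sd": {"type": "number"},
          "n_high_cnv_regions": {"type": "integer", "minimum": 0},
          "stats": {
            "type": "object",
            "properties": {
              "permutation": {"type": "object"},
              "mc_intra_inter": {"type": "object"},
              "nearest_element": {"type": "object"},
              "linearized_points": {"type": "integer"}
            }
          },
          "longread": {
            "type": "object",
            "properties": {
              "n_reads": {"type": "integer"},
              "n_element_reads": {"type": "integer"},
              "n_calls": {"type": "integer"},
              "n_inter_calls": {"type": "integer"},
              "n_truth_inter": {"type": "integer"},
              "precision_inter": {"type": "number"},
              "recall_inter": {"type": "number"}
            }
          }
        }
      }
    }
  },
  "$defs": {
    "correlation": {
      "type": "object",
      "properties": {
        "level": {"type": "string"},
        "r_squared": {"type": "number"},
        "slope": {"type": "number"},
        "intercept": {"type": "number"},
        "n_points": {"type": "integer"}
      }
    }
  }
}
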