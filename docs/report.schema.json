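{
  "type": "object",
  "required": [
    "format",
    "version",
    "config",
    "input_digests",
    "sample_id",
    "final_subtype",
    "outlier_flag",
    "outlier_rule",
    "levels"
  ],
  "properties": {
    "format": {
      "type": "string",
      "const": "subtypepredict-report"
    },
    "version": {
      "type": "string"
    },
    "config": {
      "type": "object"
    },
    "input_digests": {
      "type": "object"
    },
    "sample_id": {
      "type": "string"
    },
    "final_subtype": {
      "type": "string"
    },
    "outlier_flag": {
      "type": "boolean"
    },
    "outlier_rule": {
      "type": "string"
    },
    "levels": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "node_id",
          "assigned_child",
          "probabilities",
          "distances",
          "relative_distances",
          "pc3_unknown",
          "pc3_reference",
          "reference_children",
          "warnings"
        ],
        "properties": {
          "node_id": {
            "type": "string"
          },
          "assigned_child": {
            "type": "string"
          },
          "probabilities": {
            "type": "object",
            "values": {
              "type": "number"
            }
          },
          "distances": {
            "type": "object",
            "values": {
              "type": "number"
            }
          },
          "relative_distances": {
            "type": "object",
            "values": {
              "type": "number"
            }
          },
          "pc3_unknown": {
            "type": "array",
            "items": {
              "type": "number"
            }
          },
          "pc3_reference": {
            "type": "object"
          },
          "reference_children": {
            "type": "object"
          },
          "warnings": {
            "type": "array",
            "items": {
              "type": "string"
            }
          }
        }
      }
    }
  }
}
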