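{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "draize-miner dossier collection",
  "type": "object",
  "required": ["format", "version", "substances"],
  "properties": {
    "format": {"const": "draize-miner-collection"},
    "version": {"const": 1},
    "substances": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["id", "studies"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "dossier_category": {
            "enum": ["TYPE1", "TYPE2A", "TYPE2B", "NON_IRRITANT", "UNKNOWN"]
          },
          "hazards": {
            "type": "object",
            "propertyNames": {"pattern": "^H[0-9]{3}$"},
            "additionalProperties": {"enum": ["POSITIVE", "NEGATIVE", "UNKNOWN"]}
          },
          "fingerprint": {
            "type": "object",
            "oneOf": [
              {"required": ["bits"],
               "properties": {"bits": {"type": "string", "pattern": "^[01]+$"}}},
              {"required": ["hex", "length"],
               "properties": {"hex": {"type": "string",
                                      "pattern": "^[0-9a-fA-F]+$"},
                              "length": {"type": "integer", "minimum": 1}}}
            ]
          },
          "studies": {
            "type": "array",
            "items": {
              "type": "object",
              "required": ["study_num"],
              "properties": {
                "study_num": {"type": "integer", "minimum": 1},
                "cornea": {"type": "number", "minimum": 0, "maximum": 4},
                "iris": {"type": "number", "minimum": 0, "maximum": 2},
                "conjunctivae": {"type": "number", "minimum": 0, "maximum": 3},
                "chemosis": {"type": "number", "minimum": 0, "maximum": 4},
                "reversibility_days": {
                  "type": "object",
                  "propertyNames": {
                    "enum": ["cornea", "iris", "conjunctivae", "chemosis"]
                  },
                  "additionalProperties": {
                    "oneOf": [{"type": "integer", "minimum": 0},
                              {"const": "NOT_REVERSED"}]
                  }
                },
                "verdict_text": {"type": "string"},
                "reliability": {"type": "integer", "minimum": 1, "maximum": 4},
                "guideline": {
                  "enum": ["TG405_INVIVO", "TG405_READACROSS", "TG437",
                           "TG438", "OTHER"]
                }
              }
            }
          }
        }
      }
    }
  }
}
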