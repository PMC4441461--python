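{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/ahp-decide/hierarchy.schema.json",
  "title": "AHP decision hierarchy model file",
  "type": "object",
  "required": ["goal", "objectives", "alternatives"],
  "additionalProperties": false,
  "properties": {
    "goal": {"type": "string", "minLength": 1},
    "objectives": {
      "type": "array",
      "minItems": 1,
      "items": {"$ref": "#/$defs/objective"}
    },
    "alternatives": {
      "type": "array",
      "minItems": 2,
      "items": {"type": "string", "minLength": 1}
    },
    "context": {"type": "string"}
  },
  "$defs": {
    "objective": {
      "oneOf": [
        {"type": "string", "minLength": 1},
        {
          "type": "object",
          "required": ["name"],
          "additionalProperties": false,
          "properties": {
            "name": {"type": "string", "minLength": 1},
            "children": {
              "type": "array",
              "items": {"$ref": "#/$defs/objective"}
            }
          }
        }
      ]
    }
  }
}
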