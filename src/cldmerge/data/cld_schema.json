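{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "CLD",
  "description": "One community causal loop diagram as signed directed edges.",
  "type": "object",
  "required": ["cld_id", "links"],
  "properties": {
    "cld_id": {"type": "string", "minLength": 1},
    "variables": {
      "type": "array",
      "items": {"type": "string", "minLength": 1},
      "description": "All variables, including isolated ones; link endpoints may be omitted here."
    },
    "links": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["source", "target", "polarity"],
        "properties": {
          "source": {"type": "string", "minLength": 1},
          "target": {"type": "string", "minLength": 1},
          "polarity": {"enum": [1, -1]}
        }
      }
    }
  }
}
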