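{
  "$id": "spikebench/config",
  "title": "Network specification",
  "type": "object",
  "required": ["populations", "projections"],
  "properties": {
    "populations": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "N", "drive"],
        "properties": {
          "name": {"type": "string"},
          "N": {"type": "integer"},
          "params": {"type": "object"},
          "drive": {"type": "object", "required": ["mode"]}
        }
      }
    },
    "projections": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["pre", "post", "weight", "delay"],
        "properties": {
          "pre": {"type": "string"},
          "post": {"type": "string"},
          "p": {"type": "number"},
          "K": {"type": "integer"},
          "weight": {"type": "object", "required": ["mean", "sd"]},
          "delay": {"type": "object", "required": ["mean", "sd"]}
        }
      }
    }
  }
}
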