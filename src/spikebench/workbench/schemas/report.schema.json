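{
  "$id": "spikebench/report",
  "title": "Protocol report",
  "type": "object",
  "required": ["manifest"],
  "properties": {
    "manifest": {
      "type": "object",
      "required": ["protocol", "seeds", "h_b_ms", "backends", "version",
                   "phase_durations_s"],
      "properties": {
        "protocol": {"type": "string"},
        "seeds": {"type": "array"},
        "h_b_ms": {"type": "number"},
        "backends": {"type": "array"},
        "version": {"type": "string"},
        "phase_durations_s": {"type": "object"}
      }
    }
  }
}
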