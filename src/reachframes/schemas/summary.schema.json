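{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "reachframes experiment summary",
  "type": "object",
  "required": ["name", "seed", "config", "results"],
  "properties": {
    "name": {"type": "string"},
    "seed": {"type": "integer"},
    "config": {"type": "object"},
    "results": {"type": "object"}
  }
}
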