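{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Forward link index: compound_id -> map-covered target gene symbols",
  "type": "object",
  "required": ["header", "compounds"],
  "properties": {
    "header": {
      "type": "object",
      "properties": {
        "format": {"type": "string"},
        "version": {"type": "string"},
        "map_checksum": {"type": ["string", "null"]},
        "source_tables": {"type": "array", "items": {"type": "string"}},
        "built_at": {"type": ["string", "null"]},
        "gene_like_only": {"type": "boolean"},
        "n_dropped_offmap": {"type": "integer", "minimum": 0}
      }
    },
    "compounds": {
      "type": "object",
      "additionalProperties": {
        "type": "array",
        "items": {"type": "string"},
        "uniqueItems": true
      }
    }
  }
}
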