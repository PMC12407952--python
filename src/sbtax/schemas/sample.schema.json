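{
  "$id": "sbtax/sample/v1",
  "title": "Sample record",
  "version": 1,
  "type": "object",
  "required": ["sample_id"],
  "properties": {
    "sample_id": {"type": "string"},
    "dataset_id": {"type": "string"},
    "ecosystem": {"type": "string"},
    "ecosystem_category": {"type": "string"},
    "ecosystem_type": {"type": "string"},
    "ecosystem_subtype": {"type": "string"},
    "specific_ecosystem": {"type": "string"},
    "sequencing_platform": {"type": "string"},
    "age": {"type": "number", "minimum": 0},
    "age_category": {"type": "string"},
    "gender": {"type": "string"},
    "country": {"type": "string"},
    "location": {"type": "string"},
    "disease": {"type": "string"}
  }
}
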