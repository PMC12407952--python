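{
  "$id": "sbtax/genome/v1",
  "title": "Genome record",
  "version": 1,
  "type": "object",
  "required": ["metasbt_id", "genome_id", "genome_type"],
  "properties": {
    "metasbt_id": {"type": "string"},
    "genome_id": {"type": "string"},
    "sample_id": {"type": "string"},
    "dataset_id": {"type": "string"},
    "genome_type": {"type": "string", "enum": ["reference", "MAG"]},
    "taxonomy": {"type": "string", "format": "lineage"},
    "completeness": {"type": "number", "minimum": 0, "maximum": 100},
    "contamination": {"type": "number", "minimum": 0, "maximum": 100},
    "strain_heterogeneity": {"type": "number", "minimum": 0, "maximum": 100}
  }
}
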