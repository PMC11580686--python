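{
  "$comment": "Structural schema for lrqc MetricsReport JSON (schema_version 1.0). Minimal dialect: required keys plus primitive types; a type list marks a nullable field.",
  "type": "object",
  "required": [
    "dataset_id",
    "platform",
    "parameters",
    "hic",
    "linked",
    "evenness",
    "assembly",
    "qc",
    "tool_version",
    "schema_version"
  ],
  "properties": {
    "dataset_id": {"type": "string"},
    "platform": {"type": "string"},
    "parameters": {"type": "object"},
    "hic": {
      "type": ["object", "null"],
      "required": [
        "n_pairs",
        "unmapped_rate",
        "duplication_rate",
        "ici_rate",
        "total_accessibility"
      ],
      "properties": {
        "n_pairs": {"type": "integer"},
        "n_unmapped": {"type": "integer"},
        "n_duplicate": {"type": "integer"},
        "n_inter": {"type": "integer"},
        "n_intra": {"type": "integer"},
        "unmapped_rate": {"type": "number"},
        "duplication_rate": {"type": "number"},
        "ici_rate": {"type": "number"},
        "total_accessibility": {"type": "number"},
        "ici_conditional_rate": {"type": ["number", "null"]},
        "association": {"type": ["object", "null"]}
      }
    },
    "linked": {
      "type": ["object", "null"],
      "required": ["n_reads", "unmapped_rate", "duplication_rate", "total_accessibility"],
      "properties": {
        "n_reads": {"type": "integer"},
        "n_read_pairs": {"type": "integer"},
        "unmapped_rate": {"type": "number"},
        "duplication_rate": {"type": "number"},
        "total_accessibility": {"type": "number"},
        "molecule_n50": {"type": ["integer", "null"]},
        "reads_per_molecule_n50_ge3": {"type": ["integer", "null"]},
        "reads_per_molecule_n50_ge5": {"type": ["integer", "null"]},
        "clustered_read_pct": {"type": ["number", "null"]},
        "collision_rate": {"type": ["number", "null"]}
      }
    },
    "evenness": {
      "type": ["object", "null"],
      "required": ["mean", "variance", "unevenness"],
      "properties": {
        "mean": {"type": "number"},
        "variance": {"type": "number"},
        "unevenness": {"type": "number"},
        "unevenness_exact": {"type": "number"},
        "n_sites": {"type": "integer"},
        "degenerate": {"type": "boolean"}
      }
    },
    "assembly": {"type": ["object", "null"]},
    "qc": {"type": "object"},
    "tool_version": {"type": "string"},
    "schema_version": {"type": "string"}
  }
}
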