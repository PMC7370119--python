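{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "RNA-modification census, JSON dialect",
  "type": "object",
  "required": ["version", "source_note", "records"],
  "additionalProperties": false,
  "properties": {
    "version": {"type": "string"},
    "source_note": {"type": "string"},
    "records": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["short_name", "ascii_alias", "full_name", "status"],
        "additionalProperties": false,
        "properties": {
          "short_name": {"type": "string"},
          "ascii_alias": {"type": "string"},
          "full_name": {"type": "string"},
          "status": {"type": "string", "enum": ["placed", "unplaced", "nascent"]},
          "root_base": {"type": "string", "enum": ["A", "C", "G", "U"]},
          "parent": {"type": "string"},
          "alt_parents": {"type": "array", "items": {"type": "string"}},
          "kingdoms": {
            "type": "array",
            "items": {"type": "string", "enum": ["eukarya", "bacteria", "archaea"]}
          },
          "rna_classes": {
            "type": "array",
            "items": {
              "type": "string",
              "enum": ["tRNA", "rRNA", "mRNA", "lncRNA", "snRNA", "snoRNA",
                       "miRNA", "piRNA", "tsRNA", "viral"]
            }
          },
          "trna_positions": {"type": "array", "items": {"type": "string"}},
          "mrna_regions": {
            "type": "array",
            "items": {
              "type": "string",
              "enum": ["5'UTR", "CDS", "near-start", "near-stop", "3'UTR",
                       "cap-adjacent", "internal-exon"]
            }
          },
          "motifs": {"type": "array", "items": {"type": "string"}},
          "writers": {"type": "array", "items": {"type": "string"}},
          "readers": {"type": "array", "items": {"type": "string"}},
          "erasers": {"type": "array", "items": {"type": "string"}},
          "reversible": {"type": "string", "enum": ["yes", "no", "unknown"]},
          "stoichiometry_note": {"type": "string"},
          "notes": {"type": "string"},
          "refs": {"type": "array", "items": {"type": "string"}}
        }
      }
    }
  }
}
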