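{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "polyamp locus specification",
  "description": "Reference allele haplotypes of one amplified locus, their gene models, and the sgRNAs placed on it. Coordinates are 0-based half-open.",
  "type": "object",
  "required": ["locus_id", "alleles"],
  "properties": {
    "locus_id": {"type": "string", "minLength": 1},
    "anchor": {
      "type": "string",
      "description": "Allele id used as the common alignment frame; defaults to the first allele."
    },
    "alleles": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["id", "gene_model"],
        "properties": {
          "id": {"type": "string", "minLength": 1},
          "seq": {"type": "string", "pattern": "^[ACGTNacgtn]+$"},
          "fasta": {"type": "string", "description": "FASTA path relative to this file"},
          "fasta_id": {"type": "string"},
          "gene_model": {
            "type": "object",
            "properties": {
              "exons": {
                "type": "array",
                "items": {
                  "type": "array",
                  "items": {"type": "integer", "minimum": 0},
                  "minItems": 2,
                  "maxItems": 2
                }
              },
              "strand": {"enum": ["+", "-"]},
              "cds_start_offset": {"type": "integer", "minimum": 0},
              "gff3": {"type": "string", "description": "GFF3 path relative to this file"},
              "seqid": {"type": "string"}
            }
          }
        },
        "oneOf": [{"required": ["seq"]}, {"required": ["fasta"]}]
      }
    },
    "guides": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["name", "protospacer"],
        "properties": {
          "name": {"type": "string", "minLength": 1},
          "protospacer": {"type": "string", "pattern": "^[ACGT]{20}$"},
          "pam": {"type": "string", "pattern": "^[ACGTRYSWKMBDHVN]+$"},
          "seed_len": {"type": "integer", "minimum": 1, "maximum": 20}
        }
      }
    }
  }
}
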