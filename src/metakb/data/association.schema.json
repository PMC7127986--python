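{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "Association",
  "description": "One harmonized variant interpretation as exported to NDJSON (one object per line).",
  "type": "object",
  "required": ["source", "record_id", "gene", "variants", "disease", "evidence", "raw"],
  "properties": {
    "source": {"enum": ["CGI", "CIViC", "JAX-CKB", "MMatch", "OncoKB", "PMKB"]},
    "record_id": {"type": "string"},
    "gene": {
      "type": "object",
      "required": ["symbol", "status"],
      "properties": {
        "symbol": {"type": "string"},
        "matched_via": {"enum": ["primary", "alias", null]},
        "status": {"enum": ["normalized", "ambiguous_alias", "unmatched"]}
      }
    },
    "variants": {
      "type": "array",
      "minItems": 1,
      "items": {
        "type": "object",
        "required": ["name", "category"],
        "properties": {
          "name": {"type": "string"},
          "interval": {
            "type": ["object", "null"],
            "required": ["assembly", "chromosome", "start", "end"],
            "properties": {
              "assembly": {"enum": ["GRCh37", "GRCh38"]},
              "chromosome": {"type": "string", "minLength": 1},
              "start": {"type": "integer", "minimum": 0},
              "end": {"type": "integer", "minimum": 0},
              "ref_allele": {"type": "string"},
              "alt_allele": {"type": "string"}
            }
          },
          "hgvs_g": {"type": ["string", "null"]},
          "allele_key": {"type": ["string", "null"]},
          "category": {"enum": ["allele_specific", "categorical", "unresolved"]}
        }
      }
    },
    "disease": {
      "type": "object",
      "required": ["label", "mapping_status"],
      "properties": {
        "doid": {"type": ["string", "null"]},
        "label": {"type": "string"},
        "topnode": {"type": ["string", "null"]},
        "mapping_status": {"enum": ["mapped", "fallback_cancer", "unmapped"]},
        "needs_review": {"type": "boolean"}
      }
    },
    "drugs": {
      "type": ["object", "null"],
      "required": ["components", "is_combination"],
      "properties": {
        "components": {
          "type": "array",
          "items": {
            "type": "object",
            "required": ["input_name"],
            "properties": {
              "input_name": {"type": "string"},
              "normalized_id": {"type": ["string", "null"]},
              "normalized_label": {"type": ["string", "null"]}
            }
          }
        },
        "is_combination": {"type": "boolean"}
      }
    },
    "evidence": {
      "type": "object",
      "required": ["source_level", "harmonized_level", "tier", "direction", "documents"],
      "properties": {
        "source_level": {"type": "string"},
        "harmonized_level": {"enum": ["A", "B", "C", "D"]},
        "tier": {"enum": ["I", "II"]},
        "direction": {"enum": ["supports", "does_not_support", "conflicting", "unstated"]},
        "documents": {"type": "array", "items": {"type": "string"}, "uniqueItems": true}
      }
    },
    "raw": {
      "type": "object",
      "required": ["source", "record_id", "payload"],
      "properties": {
        "source": {"enum": ["CGI", "CIViC", "JAX-CKB", "MMatch", "OncoKB", "PMKB"]},
        "record_id": {"type": "string"},
        "payload": {"type": "object"}
      }
    }
  }
}
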