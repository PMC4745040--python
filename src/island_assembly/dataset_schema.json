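{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "IslandDataset",
  "description": "An island community dataset: island age, mainland pool composition and one record per independent colonisation. All times are in million years before present.",
  "type": "object",
  "required": ["island_age", "M", "class_fractions"],
  "additionalProperties": false,
  "properties": {
    "island_age": {
      "type": "number",
      "exclusiveMinimum": 0,
      "description": "Age of the island in My before present."
    },
    "M": {
      "type": "integer",
      "exclusiveMinimum": 0,
      "description": "Mainland species pool size."
    },
    "class_fractions": {
      "type": "object",
      "description": "Fraction of the mainland pool per lineage class; fractions sum to 1.",
      "additionalProperties": {"type": "number", "minimum": 0}
    },
    "colonists": {
      "type": "array",
      "items": {"$ref": "#/$defs/colonist"}
    }
  },
  "$defs": {
    "colonist": {
      "type": "object",
      "required": ["label", "status", "lineage_class"],
      "additionalProperties": false,
      "properties": {
        "label": {"type": "string", "description": "Unique record identifier."},
        "status": {
          "type": "integer",
          "enum": [1, 2, 3, 4, 5],
          "description": "1 = no extant island descendants; 2 = non-endemic present, colonisation time is an upper bound; 3 = non-endemic present, colonisation time known; 4 = endemic clade, mainland relative absent; 5 = endemic clade plus re-immigrated non-endemic mainland relative."
        },
        "lineage_class": {"type": "string"},
        "colonisation_time": {
          "type": ["number", "null"],
          "description": "Colonisation age in My before present (upper bound for status 2; null for status 1)."
        },
        "max_age": {
          "type": "boolean",
          "description": "True exactly when the colonisation time is an upper bound (status 2)."
        },
        "branching_times": {
          "type": "array",
          "items": {"type": "number", "exclusiveMinimum": 0},
          "description": "In-situ cladogenesis ages, strictly decreasing, all younger than the colonisation time (statuses 4-5 only)."
        },
        "n_missing": {
          "type": "integer",
          "minimum": 0,
          "description": "Extant island species of this colonist without phylogenetic data."
        }
      }
    }
  }
}
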