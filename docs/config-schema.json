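{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "smallarea run configuration (YAML); CLI flags override these keys",
  "type": "object",
  "additionalProperties": false,
  "properties": {
    "seed": {"type": "integer", "description": "master seed for all randomness"},
    "rows": {"type": "integer", "minimum": 1, "description": "simulate: lattice rows"},
    "cols": {"type": "integer", "minimum": 1, "description": "simulate: lattice cols"},
    "simulation": {
      "type": "object",
      "description": "keyword arguments for smallarea.SimulationConfig",
      "properties": {
        "age_groups": {"type": "array", "items": {"type": "string"}},
        "age_shares": {"type": "array", "items": {"type": "number"}},
        "age_baseline_per_100k": {"type": "array", "items": {"type": "number"}},
        "years": {"type": "array", "items": {"type": "integer"}},
        "spatial_sd": {"type": "number", "minimum": 0},
        "temporal_sd": {"type": "number", "minimum": 0},
        "pop_range": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2},
        "stage_fraction": {"type": "number", "minimum": 0, "maximum": 1},
        "mortality_ratio": {"type": "number", "minimum": 0},
        "overdispersion_sd": {"type": "number", "minimum": 0}
      }
    },
    "site": {
      "type": "string",
      "enum": ["colorectal", "breast", "cervical", "liver", "lung",
               "melanoma", "prostate", "non_hodgkin_lymphoma"]
    },
    "outcome": {"type": "string", "enum": ["incidence", "late_stage", "mortality"]},
    "sex": {"type": "string", "description": "'all' or a sex label in the registry"},
    "race": {"type": "string", "description": "'all' or a race label in the registry"},
    "model": {
      "type": "object",
      "properties": {
        "chains": {"type": "integer", "minimum": 1},
        "iterations": {"type": "integer", "minimum": 2},
        "burn_in": {"type": "integer", "minimum": 0},
        "thin": {"type": "integer", "minimum": 1}
      }
    },
    "standard_population": {
      "type": "array",
      "items": {"type": "number", "minimum": 0},
      "description": "age weights summing to 1; default is flat over the fixture's 4 groups"
    },
    "year": {"type": "integer", "description": "summarize: year effect to report at"},
    "hotspot_fraction": {"type": "number", "exclusiveMinimum": 0, "exclusiveMaximum": 1},
    "suppression_threshold": {"type": "integer", "minimum": 0},
    "style": {
      "type": "string",
      "enum": ["YlGnBu", "YlOrRd", "GnBu", "BuPu", "PuOr", "BrBG"]
    }
  }
}
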