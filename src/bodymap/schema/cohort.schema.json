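{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "bodymap cohort",
 "description": "One study cohort: subjects with outlined body concerns on a shared manikin raster, optional avatar slider settings and tape measurements. Coordinates are 0-based pixels, origin top-left, x rightward, y downward.",
 "type": "object",
 "required": ["subjects"],
 "properties": {
  "format": {"const": "bodymap-cohort"},
  "version": {"type": "integer"},
  "raster_dims": {
   "type": "array", "items": {"type": "integer", "minimum": 1},
   "minItems": 2, "maxItems": 2,
   "description": "[width, height] in pixels"
  },
  "vocabulary": {
   "type": "object",
   "properties": {
    "concern_types": {"type": "array", "items": {"type": "string"}},
    "affects": {"type": "array", "items": {"type": "string"}}
   }
  },
  "subjects": {
   "type": "array", "minItems": 1,
   "items": {
    "type": "object",
    "required": ["id", "group"],
    "properties": {
     "id": {"type": "string"},
     "group": {"type": "string", "minLength": 1},
     "concerns": {
      "type": "array",
      "items": {
       "type": "object",
       "required": ["polygon"],
       "properties": {
        "polygon": {
         "type": "array", "minItems": 3,
         "items": {"type": "array", "items": {"type": "number"}, "minItems": 2, "maxItems": 2}
        },
        "concern_types": {"type": "array", "items": {"type": "string"}},
        "affects": {
         "type": "array",
         "items": {
          "type": "object",
          "required": ["label"],
          "properties": {
           "label": {"type": "string"},
           "valence": {"enum": ["negative", "neutral_positive", "unclassified", ""]}
          }
         }
        },
        "intensity": {"type": "number", "minimum": 0, "maximum": 100}
       }
      }
     },
     "avatar": {
      "type": "object",
      "properties": {
       "sliders": {
        "type": "object",
        "additionalProperties": {"type": "number", "minimum": 0, "maximum": 1}
       }
      }
     },
     "measured": {
      "type": "object",
      "properties": {
       "sizes_cm": {
        "type": "object",
        "additionalProperties": {"type": "number", "exclusiveMinimum": 0}
       }
      }
     },
     "demographics": {"type": "object"},
     "usability": {"type": "object", "additionalProperties": {"type": "number"}}
    }
   }
  }
 }
}
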