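{
  "$defs": {
    "Gene": {
      "enum": [
        "CYP2C19",
        "CYP2D6"
      ],
      "title": "Gene",
      "type": "string"
    },
    "GuidelineRule": {
      "additionalProperties": false,
      "description": "One guideline cell: medication x gene x phenotype.",
      "properties": {
        "adr_risk": {
          "default": false,
          "title": "Adr Risk",
          "type": "boolean"
        },
        "dose_adjust_percent": {
          "anyOf": [
            {
              "type": "number"
            },
            {
              "maxItems": 2,
              "minItems": 2,
              "prefixItems": [
                {
                  "type": "number"
                },
                {
                  "type": "number"
                }
              ],
              "type": "array"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Dose Adjust Percent"
        },
        "gene": {
          "$ref": "#/$defs/Gene"
        },
        "inefficacy_risk": {
          "default": false,
          "title": "Inefficacy Risk",
          "type": "boolean"
        },
        "medication": {
          "title": "Medication",
          "type": "string"
        },
        "note": {
          "anyOf": [
            {
              "type": "string"
            },
            {
              "type": "null"
            }
          ],
          "default": null,
          "title": "Note"
        },
        "phenotype": {
          "anyOf": [
            {
              "$ref": "#/$defs/Phenotype"
            },
            {
              "const": "default",
              "type": "string"
            }
          ],
          "title": "Phenotype"
        },
        "recommendation": {
          "$ref": "#/$defs/Recommendation"
        },
        "source": {
          "enum": [
            "CPIC",
            "DPWG"
          ],
          "title": "Source",
          "type": "string"
        }
      },
      "required": [
        "medication",
        "gene",
        "phenotype",
        "recommendation",
        "source"
      ],
      "title": "GuidelineRule",
      "type": "object"
    },
    "Phenotype": {
      "enum": [
        "PM",
        "IM",
        "NM",
        "RM",
        "UM",
        "Indeterminate"
      ],
      "title": "Phenotype",
      "type": "string"
    },
    "Recommendation": {
      "enum": [
        "standard",
        "dose_adjust",
        "dose_adjust_or_alternative",
        "alternative"
      ],
      "title": "Recommendation",
      "type": "string"
    }
  },
  "additionalProperties": false,
  "description": "Top-level shape of the YAML knowledge-base file.",
  "properties": {
    "medication_gene_map": {
      "additionalProperties": {
        "additionalProperties": {
          "enum": [
            "primary",
            "dual"
          ],
          "type": "string"
        },
        "propertyNames": {
          "$ref": "#/$defs/Gene"
        },
        "type": "object"
      },
      "title": "Medication Gene Map",
      "type": "object"
    },
    "rules": {
      "items": {
        "$ref": "#/$defs/GuidelineRule"
      },
      "title": "Rules",
      "type": "array"
    },
    "sources": {
      "items": {
        "type": "string"
      },
      "title": "Sources",
      "type": "array"
    },
    "synonyms": {
      "additionalProperties": {
        "type": "string"
      },
      "title": "Synonyms",
      "type": "object"
    },
    "version": {
      "title": "Version",
      "type": "string"
    }
  },
  "required": [
    "version",
    "medication_gene_map",
    "rules"
  ],
  "title": "_KBFile",
  "type": "object"
}
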