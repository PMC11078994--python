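{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "$id": "https://example.org/duc/duc-profile.schema.json",
  "title": "Digital Use Conditions profile",
  "description": "A DUC profile: optional contextual header fields plus an ordered array of at least one independent condition statement (conditionTerm + rule + scope + optional conditionParameters).",
  "type": "object",
  "properties": {
    "profileId": {"type": "string", "format": "uri"},
    "profileVersion": {
      "type": "string",
      "pattern": "^(0|[1-9]\\d*)\\.(0|[1-9]\\d*)\\.(0|[1-9]\\d*)(-[0-9A-Za-z][0-9A-Za-z.-]*)?(\\+[0-9A-Za-z][0-9A-Za-z.-]*)?$"
    },
    "profileName": {"type": "string"},
    "ducVersion": {"type": "string"},
    "creationDate": {"type": "string", "format": "date"},
    "lastUpdated": {"type": "string", "format": "date"},
    "assets": {
      "type": "array",
      "items": {"$ref": "#/$defs/asset"}
    },
    "permissionMode": {
      "enum": [
        "All unstated conditions are Forbidden",
        "All unstated conditions are Permitted"
      ]
    },
    "language": {"type": "string", "pattern": "^[A-Za-z]{3}$"},
    "statements": {
      "type": "array",
      "minItems": 1,
      "items": {"$ref": "#/$defs/statement"}
    }
  },
  "required": ["statements"],
  "$defs": {
    "termRef": {
      "type": "object",
      "properties": {
        "label": {"type": "string"},
        "uri": {"type": "string", "format": "uri"}
      },
      "anyOf": [{"required": ["label"]}, {"required": ["uri"]}]
    },
    "conditionParameter": {
      "type": "object",
      "properties": {
        "label": {"type": "string"},
        "uri": {"type": "string", "format": "uri"},
        "value": {"type": ["number", "string"]}
      },
      "anyOf": [
        {"required": ["label"]},
        {"required": ["uri"]},
        {"required": ["value"]}
      ]
    },
    "statement": {
      "type": "object",
      "properties": {
        "conditionTerm": {"$ref": "#/$defs/termRef"},
        "rule": {
          "enum": ["Obligatory", "Permitted", "Forbidden", "No Requirement"]
        },
        "scope": {
          "enum": ["Whole of asset", "Part of asset"],
          "default": "Whole of asset"
        },
        "conditionParameters": {
          "anyOf": [
            {
              "type": "array",
              "items": {"$ref": "#/$defs/conditionParameter"}
            },
            {"$ref": "#/$defs/conditionParameter"}
          ]
        }
      },
      "required": ["conditionTerm", "rule"]
    },
    "asset": {
      "type": "object",
      "properties": {
        "assetName": {"type": "string"},
        "assetDescription": {"type": "string"},
        "assetReferences": {"type": "array", "items": {"type": "string"}},
        "assetURI": {"type": "string", "format": "uri"}
      },
      "minProperties": 1
    }
  }
}
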