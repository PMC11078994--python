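{
  "statements": [
    {
      "conditionTerm": {
        "label": "General research use"
      },
      "rule": "Permitted",
      "scope": "Whole of asset"
    },
    {
      "conditionTerm": {
        "label": "Country"
      },
      "rule": "Permitted",
      "scope": "Whole of asset",
      "conditionParameters": [
        {
          "label": "the United Kingdom"
        }
      ]
    },
    {
      "conditionTerm": {
        "label": "Time limit on use"
      },
      "rule": "Obligatory",
      "scope": "Whole of asset",
      "conditionParameters": [
        {
          "label": "months",
          "value": 12
        }
      ]
    }
  ]
}
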