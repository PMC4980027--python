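{
  "$defs": {
    "WarningRecord": {
      "properties": {
        "indicator_id": {
          "title": "Indicator Id",
          "type": "string"
        },
        "start": {
          "title": "Start",
          "type": "integer"
        },
        "end": {
          "title": "End",
          "type": "integer"
        },
        "side": {
          "title": "Side",
          "type": "string"
        },
        "mean_p": {
          "title": "Mean P",
          "type": "number"
        }
      },
      "required": [
        "indicator_id",
        "start",
        "end",
        "side",
        "mean_p"
      ],
      "title": "WarningRecord",
      "type": "object"
    }
  },
  "description": "Serializable assessment result (the published report schema).",
  "properties": {
    "times": {
      "items": {
        "type": "integer"
      },
      "title": "Times",
      "type": "array"
    },
    "indicator_ids": {
      "items": {
        "type": "string"
      },
      "title": "Indicator Ids",
      "type": "array"
    },
    "posterior": {
      "items": {
        "type": "number"
      },
      "title": "Posterior",
      "type": "array"
    },
    "prior_chain": {
      "items": {
        "type": "number"
      },
      "title": "Prior Chain",
      "type": "array"
    },
    "likelihoods": {
      "items": {
        "items": {
          "type": "number"
        },
        "type": "array"
      },
      "title": "Likelihoods",
      "type": "array"
    },
    "warnings": {
      "default": [],
      "items": {
        "$ref": "#/$defs/WarningRecord"
      },
      "title": "Warnings",
      "type": "array"
    },
    "explained_variance": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Explained Variance"
    },
    "selected_indicators": {
      "anyOf": [
        {
          "items": {
            "type": "string"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Selected Indicators"
    },
    "share_trajectory": {
      "anyOf": [
        {
          "items": {
            "type": "number"
          },
          "type": "array"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Share Trajectory"
    },
    "config": {
      "additionalProperties": true,
      "default": {},
      "title": "Config",
      "type": "object"
    },
    "seed": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Seed"
    }
  },
  "required": [
    "times",
    "indicator_ids",
    "posterior",
    "prior_chain",
    "likelihoods"
  ],
  "title": "AssessmentReport",
  "type": "object"
}
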