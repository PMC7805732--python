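{
  "description": "Structured record of one image's trip through the pipeline.",
  "properties": {
    "image_id": {
      "title": "Image Id",
      "type": "string"
    },
    "roi": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Roi",
      "type": "object"
    },
    "foreground_pixels": {
      "title": "Foreground Pixels",
      "type": "integer"
    },
    "dice_vs_truth": {
      "anyOf": [
        {
          "type": "number"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Dice Vs Truth"
    },
    "features": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Features",
      "type": "object"
    },
    "predicted_grade": {
      "title": "Predicted Grade",
      "type": "string"
    },
    "config_fingerprint": {
      "title": "Config Fingerprint",
      "type": "string"
    },
    "seed": {
      "title": "Seed",
      "type": "integer"
    },
    "stage_seconds": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Stage Seconds",
      "type": "object"
    }
  },
  "required": [
    "image_id",
    "roi",
    "foreground_pixels",
    "features",
    "predicted_grade",
    "config_fingerprint",
    "seed",
    "stage_seconds"
  ],
  "title": "RunReport",
  "type": "object"
}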