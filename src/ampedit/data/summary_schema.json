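{
  "description": "Machine-readable twin of the outcome pie: validated summary JSON.",
  "properties": {
    "reference_id": {
      "title": "Reference Id",
      "type": "string"
    },
    "guide_id": {
      "title": "Guide Id",
      "type": "string"
    },
    "profile": {
      "title": "Profile",
      "type": "string"
    },
    "total_reads": {
      "title": "Total Reads",
      "type": "integer"
    },
    "merged_pairs": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Merged Pairs"
    },
    "merge_failures": {
      "anyOf": [
        {
          "type": "integer"
        },
        {
          "type": "null"
        }
      ],
      "default": null,
      "title": "Merge Failures"
    },
    "qc_discarded": {
      "title": "Qc Discarded",
      "type": "integer"
    },
    "unassigned": {
      "title": "Unassigned",
      "type": "integer"
    },
    "counts": {
      "additionalProperties": {
        "type": "integer"
      },
      "title": "Counts",
      "type": "object"
    },
    "fractions_pct": {
      "additionalProperties": {
        "type": "number"
      },
      "title": "Fractions Pct",
      "type": "object"
    },
    "mmej_pct": {
      "title": "Mmej Pct",
      "type": "number"
    },
    "editing_efficiency_pct": {
      "title": "Editing Efficiency Pct",
      "type": "number"
    }
  },
  "required": [
    "reference_id",
    "guide_id",
    "profile",
    "total_reads",
    "qc_discarded",
    "unassigned",
    "counts",
    "fractions_pct",
    "mmej_pct",
    "editing_efficiency_pct"
  ],
  "title": "SummaryModel",
  "type": "object"
}
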