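{
  "$schema": "http://json-schema.org/draft-07/schema#",
  "title": "cenfuse full-analysis summary",
  "type": "object",
  "required": [
    "version",
    "input",
    "reference",
    "parameters",
    "n_monomers",
    "monomers",
    "blocks",
    "insertions",
    "provenance",
    "motif_hits",
    "spectrum",
    "saturation",
    "newick",
    "candidates"
  ],
  "properties": {
    "version": {"type": "string"},
    "input": {"type": "string"},
    "reference": {"type": "string"},
    "parameters": {
      "type": "object",
      "required": [
        "min_identity",
        "min_coverage",
        "min_block_identity",
        "max_intra_gap",
        "motif",
        "max_mismatch",
        "saturation_threshold",
        "seed"
      ]
    },
    "n_monomers": {"type": "integer"},
    "monomers": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["index", "start", "end", "strand", "ref_identity", "ref_coverage"],
        "properties": {
          "index": {"type": "integer"},
          "start": {"type": "integer"},
          "end": {"type": "integer"},
          "strand": {"type": "string"},
          "ref_identity": {"type": "number"},
          "ref_coverage": {"type": "number"}
        }
      }
    },
    "blocks": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["block_id", "start", "end", "orientation", "n_members", "mean_identity"]
      }
    },
    "insertions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["start", "end", "length"]
      }
    },
    "provenance": {
      "type": ["array", "null"],
      "items": {
        "type": "object",
        "required": [
          "fused_block_id",
          "donor_label",
          "donor_block_id",
          "identity",
          "orientation_relation",
          "runner_up_identity",
          "is_tie"
        ]
      }
    },
    "motif_hits": {
      "type": "array",
      "items": {
        "type": "object",
        "required": ["block_id", "start", "strand", "window", "total_mismatches", "core_mismatches"]
      }
    },
    "spectrum": {
      "type": "object",
      "required": [
        "n_sites_compared",
        "n_substitutions",
        "n_transitions",
        "n_transversions",
        "n_deletions",
        "prop_transitions",
        "prop_transversions"
      ]
    },
    "saturation": {
      "type": ["object", "null"],
      "required": ["ts_slope", "tv_slope", "ts_saturated", "tv_saturated"]
    },
    "newick": {"type": ["string", "null"]},
    "candidates": {"type": ["array", "null"]}
  }
}
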