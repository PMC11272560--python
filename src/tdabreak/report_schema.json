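{
  "type": "object",
  "required": ["package", "version", "timestamp", "config", "results"],
  "properties": {
    "package": {"type": "string"},
    "version": {"type": "string"},
    "timestamp": {"type": "string"},
    "config": {
      "type": "object",
      "required": ["window", "max_homology_dim", "kmax", "n_permutations", "alternative", "seed"],
      "properties": {
        "window": {"type": "integer"},
        "max_homology_dim": {"type": "integer"},
        "kmax": {"type": "integer"},
        "n_permutations": {"type": "integer"},
        "alternative": {"type": "string"},
        "seed": {"type": "integer"}
      }
    },
    "results": {
      "type": "object",
      "patternProperties": {
        "^[0-2]$": {
          "type": "object",
          "required": ["observed_hfd", "p_value", "n_permutations", "mean_permuted_hfd"],
          "properties": {
            "observed_hfd": {"type": "number"},
            "p_value": {"type": "number"},
            "n_permutations": {"type": "integer"},
            "mean_permuted_hfd": {"type": "number"}
          }
        }
      }
    }
  }
}
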