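{
  "type": "object",
  "required": ["provenance", "mode", "exclusions"],
  "properties": {
    "mode": {"type": "string"},
    "provenance": {
      "type": "object",
      "required": ["config_hash", "seed", "package_version"],
      "properties": {
        "config_hash": {"type": "string"},
        "seed": {"type": "integer"},
        "package_version": {"type": "string"}
      }
    },
    "exclusions": {
      "type": "object",
      "required": ["low_accuracy", "dot_outliers", "n_retained"],
      "properties": {
        "low_accuracy": {"type": "array"},
        "dot_outliers": {"type": "array"},
        "n_retained": {"type": "integer"}
      }
    },
    "validity": {"type": "object"},
    "contrasts": {"type": "object"},
    "acuity": {"type": "object"},
    "extrapolation": {
      "type": "object",
      "required": ["predicted_moments", "pooled_median", "pooled_mean"],
      "properties": {
        "predicted_moments": {"type": "object"},
        "pooled_median": {"type": "number"},
        "pooled_mean": {"type": "number"},
        "acceptance_rate": {"type": "number"}
      }
    },
    "correlation": {
      "type": "object",
      "required": ["n", "r", "t_stat", "p_two_sided", "bf01", "prior_scale", "evidence"],
      "properties": {
        "n": {"type": "integer"},
        "r": {"type": "number"},
        "t_stat": {"type": "number"},
        "p_two_sided": {"type": "number"},
        "bf01": {"type": "number"},
        "prior_scale": {"type": "number"},
        "evidence": {"type": "string"}
      }
    }
  }
}
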