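{
  "type": "object",
  "required": {
    "n": {"type": "integer"},
    "seed": {"type": "integer"},
    "breakpoint_age": {"type": "number"},
    "warnings": {"type": "array"},
    "trajectories": {
      "type": "object",
      "required": {
        "whole": {"type": "object"},
        "rostral": {"type": "object"},
        "caudal": {"type": "object"}
      }
    },
    "sex_comparison": {"type": "object"},
    "variance_comparison": {"type": "object"},
    "pons_vs_age": {"type": "object"},
    "pons_vs_age_tr_adjusted": {"type": "object"},
    "adjusted_regression": {"type": "object"},
    "old_vs_young_welch": {"type": "object"},
    "left_vs_right_paired": {"type": "object"},
    "voxels_vs_age": {"type": "object"},
    "qc": {
      "type": "object",
      "required": {
        "n_input": {"type": "integer"},
        "n_excluded_motion": {"type": "integer"},
        "n_excluded_negative_cr": {"type": "integer"},
        "n_retained": {"type": "integer"},
        "retained_pct": {"type": "integer"}
      }
    }
  }
}
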