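{
  "seed": 20140724,
  "n_genes": 20,
  "isoform_count_weights": [
    0.35,
    0.4,
    0.25
  ],
  "exons_per_gene": [
    1,
    6
  ],
  "exon_length_range": [
    30,
    150
  ],
  "intron_length_range": [
    50,
    500
  ],
  "domain_density": 0.7,
  "p_principal_annotated": 0.8,
  "n_variants_per_class": 100,
  "pathogenic": {
    "rel_lo": 0.02,
    "rel_hi": 0.3,
    "prefer_principal": true,
    "nmd": "free",
    "maf_lo": 0.0001,
    "maf_hi": 0.002,
    "p_singleton": 0.5
  },
  "benign": {
    "rel_lo": 0.7,
    "rel_hi": 0.98,
    "prefer_principal": false,
    "nmd": "free",
    "maf_lo": 0.01,
    "maf_hi": 0.2,
    "p_singleton": 0.0
  },
  "expression": {
    "n_samples": 50,
    "baseline_log": 3.0,
    "baseline_log_sd": 0.5,
    "nmd_effect_size": 0.5,
    "noise_sd": 0.2
  },
  "class1_model": {
    "mu": [
      0.75,
      0.5,
      3.0,
      0.85
    ],
    "sd": [
      0.2,
      0.2,
      1.5,
      0.25
    ],
    "theta": [
      0.8,
      0.7
    ]
  },
  "class0_model": {
    "mu": [
      0.35,
      0.15,
      3.0,
      0.55
    ],
    "sd": [
      0.2,
      0.2,
      1.5,
      0.25
    ],
    "theta": [
      0.35,
      0.25
    ]
  }
}
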