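{
  "type": "object",
  "required": ["report_type"],
  "properties": {
    "report_type": {
      "type": "string",
      "enum": [
        "global_fit",
        "hyperbolic_fit",
        "arrhenius_fit",
        "eyring_fit",
        "kie",
        "fad_content",
        "isotope_report"
      ]
    },
    "chosen_n_steps": {"type": "integer"},
    "rates_per_s": {"type": "array", "items": {"type": "number"}},
    "rate_se_per_s": {"type": "array", "items": {}},
    "amplitude_fractions": {"type": "array", "items": {"type": "number"}},
    "residual_ss": {"type": "number"},
    "converged": {"type": "boolean"},
    "exchange_ambiguous": {"type": "boolean"},
    "k_limit_per_s": {"type": "number"},
    "Kd_uM": {"type": "number"},
    "A_per_s": {"type": "number"},
    "Ea_kcal_mol": {"type": "number"},
    "dH_kcal_mol": {"type": "number"},
    "dS_cal_mol_K": {"type": "number"},
    "kie": {"type": "number"},
    "kie_sd": {"type": "number"},
    "protein_conc_uM": {"type": "number"},
    "fad_conc_uM": {"type": "number"},
    "fraction_bound": {"type": "number"},
    "delta_Ea_kcal_mol": {"type": "number"},
    "A_ratio": {"type": "number"}
  }
}
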