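{
  "description": "Cohort-table inputs of the 25-patient AF ablation registry: group counts and summary statistics for every reported comparison, with the published p-values for reference.",
  "proportions": [
    {"name": "prior_ablation_paf_vs_peaf", "k1": 2, "n1": 9, "k2": 13, "n2": 16, "printed_p": 0.002},
    {"name": "cardioversion_paf_vs_peaf", "k1": 2, "n1": 9, "k2": 12, "n2": 16, "printed_p": 0.005},
    {"name": "presented_in_af_paf_vs_peaf", "k1": 0, "n1": 9, "k2": 13, "n2": 16, "printed_p": 0.001},
    {"name": "noninducible_paf_vs_peaf", "k1": 6, "n1": 9, "k2": 0, "n2": 16, "printed_p": 0.001},
    {"name": "per_protocol_paf_vs_peaf", "k1": 7, "n1": 9, "k2": 5, "n2": 16, "printed_p": 0.013},
    {"name": "ffaf_denovo_vs_redo", "k1": 11, "n1": 13, "k2": 2, "n2": 8, "printed_p": 0.003},
    {"name": "ffaf_high_vs_low_egfc", "k1": 9, "n1": 10, "k2": 5, "n2": 11, "printed_p": 0.015},
    {"name": "type_i_paf_vs_peaf", "k1": 3, "n1": 9, "k2": 1, "n2": 16, "printed_p": 0.038},
    {"name": "ffaf_denovo_vs_redo_peaf", "k1": 6, "n1": 8, "k2": 1, "n2": 5, "printed_p": 0.026},
    {"name": "ffaf_denovo_vs_redo_paf", "k1": 5, "n1": 5, "k2": 1, "n2": 3, "printed_p": 0.017}
  ],
  "means": [
    {"name": "sources_per_patient_paf_vs_peaf", "m1": 0.9, "sd1": 1.2, "n1": 9, "m2": 2.2, "sd2": 1.3, "n2": 16, "printed_p": 0.011}
  ],
  "cohort": {
    "n_patients": 25,
    "egfc_median": 0.548,
    "phenotype_counts": {"I": 4, "II": 8, "III": 8, "IV": 5},
    "ffaf_by_phenotype": {"I": [3, 3], "II": [6, 7], "III": [4, 7], "IV": [1, 4]}
  }
}
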