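{
  "description": "Published responder 2x2 tables of the source study (rows = groups, a = responders group 1, b = non-responders group 1, c/d likewise group 2), with the chi-squared statistic reported alongside each table. One reported value (beta-alanine itch under TRPV1 blockade, 14 of 16 subjects, reported as 3.09) is inconsistent with any table formed from its own counts and is excluded here.",
  "chi2_tables": [
    {
      "label": "beta_alanine_pain_injection_vs_focal",
      "outcome": "pain",
      "group1": "injection (17/24)",
      "group2": "focal (11/24)",
      "a": 17, "b": 7, "c": 11, "d": 13,
      "reported_chi2": 3.09, "reported_p": "0.08"
    },
    {
      "label": "bam8_22_pain_injection_vs_focal",
      "outcome": "pain",
      "group1": "injection (14/22)",
      "group2": "focal (8/22)",
      "a": 14, "b": 8, "c": 8, "d": 14,
      "reported_chi2": 3.27, "reported_p": "0.07"
    },
    {
      "label": "chloroquine_injection_pain_vs_itch",
      "outcome": "responder",
      "group1": "pain >= 1 (7/24)",
      "group2": "itch >= 1 (10/24)",
      "a": 7, "b": 17, "c": 10, "d": 14,
      "reported_chi2": 0.82, "reported_p": "0.37"
    },
    {
      "label": "chloroquine_pain_focal_vs_injection",
      "outcome": "pain",
      "group1": "focal (2/24)",
      "group2": "injection (15/24)",
      "a": 2, "b": 22, "c": 15, "d": 9,
      "reported_chi2": 15.39, "reported_p": "<0.001"
    },
    {
      "label": "cowhage_itch_injection_vs_focal",
      "outcome": "itch",
      "group1": "injection (18/24)",
      "group2": "focal (21/24)",
      "a": 18, "b": 6, "c": 21, "d": 3,
      "reported_chi2": 1.23, "reported_p": "0.27"
    },
    {
      "label": "cowhage_pain_injection_vs_focal",
      "outcome": "pain",
      "group1": "injection (19/24)",
      "group2": "focal (11/24)",
      "a": 19, "b": 5, "c": 11, "d": 13,
      "reported_chi2": 5.69, "reported_p": "0.02"
    },
    {
      "label": "afiber_block_beta_alanine_itch_vs_pain_reduced",
      "outcome": "relevant reduction",
      "group1": "itch reduced (17/20)",
      "group2": "pain reduced (9/20)",
      "a": 17, "b": 3, "c": 9, "d": 11,
      "reported_chi2": 7.03, "reported_p": "0.01"
    },
    {
      "label": "afiber_block_bam8_22_itch_vs_pain_reduced",
      "outcome": "relevant reduction",
      "group1": "itch reduced (11/20)",
      "group2": "pain reduced (3/20)",
      "a": 11, "b": 9, "c": 3, "d": 17,
      "reported_chi2": 7.03, "reported_p": "0.01"
    },
    {
      "label": "trpa1_block_beta_alanine_itch_reduced_vs_control",
      "outcome": "relevant itch reduction",
      "group1": "A-967079 (15/16)",
      "group2": "control (0/16)",
      "a": 15, "b": 1, "c": 0, "d": 16,
      "reported_chi2": 28.23, "reported_p": "<0.001"
    },
    {
      "label": "trpa1_block_bam8_22_itch_reduced_vs_control",
      "outcome": "relevant itch reduction",
      "group1": "A-967079 (11/13)",
      "group2": "control (0/13)",
      "a": 11, "b": 2, "c": 0, "d": 13,
      "reported_chi2": 19.07, "reported_p": "<0.001"
    },
    {
      "label": "trpv1_block_bam8_22_itch_reduced_vs_control",
      "outcome": "relevant itch reduction",
      "group1": "BCTC (10/13)",
      "group2": "control (0/13)",
      "a": 10, "b": 3, "c": 0, "d": 13,
      "reported_chi2": 16.25, "reported_p": "<0.001"
    },
    {
      "label": "trpa1_block_cowhage_itch_reduced_vs_control",
      "outcome": "relevant itch reduction",
      "group1": "A-967079 (12/13)",
      "group2": "control (0/13)",
      "a": 12, "b": 1, "c": 0, "d": 13,
      "reported_chi2": 22.29, "reported_p": "<0.001"
    },
    {
      "label": "trpv1_block_cowhage_itch_reduced_vs_control",
      "outcome": "relevant itch reduction",
      "group1": "BCTC (10/13)",
      "group2": "control (0/13)",
      "a": 10, "b": 3, "c": 0, "d": 13,
      "reported_chi2": 16.25, "reported_p": "<0.001"
    }
  ],
  "fisher_tables": [
    {
      "label": "histamine_sine_wave_itch_pre_vs_post",
      "group1": "pre-histamine itch perceivers (4/15)",
      "group2": "post-histamine itch perceivers (12/15)",
      "a": 4, "b": 11, "c": 12, "d": 3,
      "reported_p": "<0.01"
    }
  ],
  "activation_fractions": [
    {
      "label": "pct_cm_activated_cowhage",
      "n_activated": 10, "n_tested": 18,
      "reported_pct": 56, "reported_precision": 0
    },
    {
      "label": "pct_cm_activated_bam8_22",
      "n_activated": 34, "n_tested": 38,
      "reported_pct": 89.5, "reported_precision": 1
    }
  ]
}
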