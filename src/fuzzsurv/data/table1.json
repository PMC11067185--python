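{
  "version": 1,
  "n": 581,
  "counts": {
    "sex": {"male": 278, "female": 303},
    "age_group": {"<41": 41, "41-60": 241, ">60": 299},
    "tumor_location": {"oral_tongue": 258, "floor_of_mouth": 53, "buccal_mucosa": 64, "alveolar_ridge": 110, "hard_palate": 13, "lip": 67, "retromolar_trigone": 16},
    "t_stage": {"T1": 98, "T2": 194, "T3": 100, "T4a": 186, "T4b": 3},
    "pn_stage": {"N0": 298, "N1": 107, "N2a": 25, "N2b": 108, "N2c": 38, "N3": 5},
    "tnm_stage": {"I": 78, "II": 109, "III": 106, "IVa": 279, "IVb": 9},
    "histologic_grade": {"well": 387, "moderate": 165, "poor": 29},
    "ln_metastasis": {"positive": 283, "negative": 298},
    "lymphovascular_invasion": {"positive": 100, "negative": 481},
    "perineural_invasion": {"positive": 138, "negative": 443},
    "margin": {"positive": 114, "close": 20, "clear": 447},
    "extranodal_extension": {"positive": 44, "negative": 537},
    "primary_treatment": {"surgery": 150, "surgery_rt": 302, "surgery_ccrt": 129},
    "locoregional_recurrence": {"local": 78, "none": 503},
    "distant_metastasis": {"lung": 29, "bone": 6, "none": 546},
    "survival_class": {"0": 154, "1": 67, "2": 33, "3": 19, "4": 6, "5": 302}
  }
}
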