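{
  "version": 1,
  "name": "oscc-clinicopathologic",
  "variables": [
    {"name": "sex", "levels": ["male", "female"]},
    {"name": "age_group", "levels": ["<41", "41-60", ">60"]},
    {"name": "tumor_location", "levels": ["oral_tongue", "floor_of_mouth", "buccal_mucosa", "alveolar_ridge", "hard_palate", "lip", "retromolar_trigone"]},
    {"name": "t_stage", "levels": ["T1", "T2", "T3", "T4a", "T4b"]},
    {"name": "pn_stage", "levels": ["N0", "N1", "N2a", "N2b", "N2c", "N3"]},
    {"name": "tnm_stage", "levels": ["I", "II", "III", "IVa", "IVb"]},
    {"name": "histologic_grade", "levels": ["well", "moderate", "poor"]},
    {"name": "ln_metastasis", "levels": ["positive", "negative"]},
    {"name": "lymphovascular_invasion", "levels": ["positive", "negative"]},
    {"name": "perineural_invasion", "levels": ["positive", "negative"]},
    {"name": "margin", "levels": ["positive", "close", "clear"]},
    {"name": "extranodal_extension", "levels": ["positive", "negative"]},
    {"name": "primary_treatment", "levels": ["surgery", "surgery_rt", "surgery_ccrt"]},
    {"name": "locoregional_recurrence", "levels": ["local", "none"]},
    {"name": "distant_metastasis", "levels": ["lung", "bone", "none"]}
  ]
}
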