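{
  "provenance": "Printed screening tallies of the published AHC cohort (ATP1A3).",
  "n_probands": 105,
  "n_sporadic": 101,
  "n_familial": 4,
  "n_variant_positive": 98,
  "n_variants": 33,
  "n_trios_tested": 93,
  "n_de_novo": 90,
  "n_inherited": 3,
  "n_screened_families": 80,
  "n_sperm_donors": 51,
  "n_aspcr_informative": 33,
  "n_origin_paternal": 29,
  "n_origin_maternal": 4
}
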