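# Comorbidity grouping table (corrected variant; package default).
#
# Maps comorbidity-group names to ICD-9-AM / ICD-10-AM code patterns.
# Pattern syntax: literal code ("427.31"), wildcard prefix ("428.x" matches
# "428" and anything beginning "428."), or inclusive range joined by an
# en dash or hyphen ("J40.x-J47.x").
#
# The cardiovascular and chronic-pulmonary lists follow the Quan et al.
# Elixhauser adaptation. A handful of published codes are obvious
# misprints (I1.0, 143.x, 150.x, I05.x-108.x, 426.6-426.28); this file uses
# the corrected forms (I11.0, I43.x, I50.x, I05.x-I08.x, 426.6-426.89).
# The verbatim published strings are preserved in
# comorbidity_groups_printed.yaml.
#
# The remaining groups are a configurable subset of the Elixhauser
# comorbidity categories; edit or extend this file to change the grouping.

groups:
  cardiovascular_disease:
    icd9:
      - "398.91"
      - "402.11"
      - "402.91"
      - "404.11"
      - "404.13"
      - "404.91"
      - "404.93"
      - "428.x"
      - "426.10"
      - "426.11"
      - "426.13"
      - "426.2–426.53"
      - "426.6–426.89"
      - "427.0"
      - "427.2"
      - "427.31"
      - "427.60"
      - "427.9"
      - "785.0"
      - "V45.0"
      - "V53.3"
      - "093.2"
      - "394.0–397.1"
      - "424.0–424.91"
      - "746.3–746.6"
      - "V42.2"
      - "V43.3"
      - "416.x"
      - "417.9"
      - "440.x"
      - "441.2"
      - "441.4"
      - "441.7"
      - "441.9"
      - "443.1–443.9"
      - "447.1"
      - "557.1"
      - "557.9"
      - "V43.4"
    icd10:
      - "I09.9"
      - "I11.0"
      - "I13.0"
      - "I13.2"
      - "I25.5"
      - "I42.0"
      - "I42.5–I42.9"
      - "I43.x"
      - "I50.x"
      - "P29.0"
      - "I44.1–I44.3"
      - "I45.6"
      - "I45.9"
      - "I47.x"
      - "R00.0"
      - "R00.1"
      - "R00.8"
      - "T82.1"
      - "Z45.0"
      - "Z95.0"
      - "A52.0"
      - "I05.x–I08.x"
      - "I09.1"
      - "I09.8"
      - "I34.x–I39.x"
      - "Q23.0–Q23.3"
      - "Z95.2–Z95.4"
      - "I26.x"
      - "I27.x"
      - "I28.0"
      - "I28.8"
      - "I28.9"
      - "I70.x"
      - "I71.x"
      - "I73.1"
      - "I73.8"
      - "I73.9"
      - "I77.1"
      - "I79.0"
      - "I79.2"
      - "K55.1"
      - "K55.8"
      - "K55.9"
      - "Z95.8"
      - "Z95.9"
  chronic_pulmonary_disease:
    icd9:
      - "416.8"
      - "416.9"
      - "490.x–505.x"
      - "506.4"
      - "508.1"
      - "508.9"
    icd10:
      - "I27.8"
      - "I27.9"
      - "J40.x–J47.x"
      - "J60.x–J67.x"
      - "J68.4"
      - "J70.1"
      - "J70.3"
  smoking:
    icd9:
      - "3051"
      - "64900"
      - "64901"
      - "64902"
      - "64903"
      - "64904"
      - "V1582"
    icd10:
      - "F17"
      - "F17.x"
      - "T65.2"
      - "P04.2"
      - "Z72.0"
      - "Z86.43"
      - "Z58.7"
  hypertension:
    icd9:
      - "401.x"
      - "402.x"
      - "403.x"
      - "404.x"
      - "405.x"
    icd10:
      - "I10"
      - "I10.x"
      - "I11.x"
      - "I12.x"
      - "I13.x"
      - "I15.x"
  diabetes:
    icd9:
      - "250.x"
    icd10:
      - "E10.x"
      - "E11.x"
      - "E13.x"
      - "E14.x"
  renal_failure:
    icd9:
      - "585.x"
      - "586.x"
      - "V56.0"
    icd10:
      - "N18.x"
      - "N19.x"
      - "Z49.0"
  liver_disease:
    icd9:
      - "570.x"
      - "571.x"
      - "572.x"
    icd10:
      - "K70.x"
      - "K72.x"
      - "K74.x"
      - "K76.x"
  hypothyroidism:
    icd9:
      - "243.x"
      - "244.x"
    icd10:
      - "E00.x–E03.x"
      - "E89.0"
  rheumatoid_arthritis:
    icd9:
      - "714.x"
      - "725.x"
    icd10:
      - "M05.x"
      - "M06.x"
      - "M32.x"
  peptic_ulcer:
    icd9:
      - "531.x–534.x"
    icd10:
      - "K25.x–K28.x"
  obesity:
    icd9:
      - "278.0"
      - "278.00"
      - "278.01"
    icd10:
      - "E66.x"
  depression:
    icd9:
      - "296.2"
      - "296.3"
      - "311"
    icd10:
      - "F32.x"
      - "F33.x"
  fluid_electrolyte:
    icd9:
      - "276.x"
    icd10:
      - "E86.x"
      - "E87.x"
  solid_tumour:
    icd9:
      - "153.x"
      - "162.x"
      - "174.x"
    icd10:
      - "C18.x"
      - "C34.x"
      - "C50.x"
  deficiency_anemia:
    icd9:
      - "280.x"
      - "285.x"
    icd10:
      - "D50.x"
      - "D64.x"
  coagulopathy:
    icd9:
      - "286.x"
    icd10:
      - "D65.x–D68.x"
  alcohol_abuse:
    icd9:
      - "303.x"
    icd10:
      - "F10.x"
  drug_abuse:
    icd9:
      - "304.x"
    icd10:
      - "F11.x–F16.x"
      - "F18.x"
      - "F19.x"
  psychoses:
    icd9:
      - "295.x"
      - "298.x"
    icd10:
      - "F20.x"
      - "F22.x–F25.x"
      - "F28"
      - "F29"
  neurological_disorder:
    icd9:
      - "332.x"
      - "345.x"
    icd10:
      - "G20"
      - "G40.x"
      - "G41.x"
  paralysis:
    icd9:
      - "342.x"
      - "344.x"
    icd10:
      - "G81.x"
      - "G82.x"
  weight_loss:
    icd9:
      - "260.x–263.x"
    icd10:
      - "E40.x–E46.x"
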