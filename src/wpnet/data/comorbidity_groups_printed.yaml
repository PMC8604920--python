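# Comorbidity grouping table — verbatim published variant.
#
# Identical to comorbidity_groups.yaml except that the cardiovascular list
# preserves the published code strings exactly, including apparent misprints
# ("I1.0", "143.x", "150.x", "I05.x–108.x", "426.6–426.28").  A range whose
# endpoints carry different alphabetic prefixes, or whose endpoints are
# reversed, parses but matches no code; the misprinted literals simply never
# match real ICD-10 codes.  Use comorbidity_groups.yaml (the default) for a
# functional mapping.

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
      - "426.6–426.28"
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
      - "I1.0"
      - "I13.0"
      - "I13.2"
      - "I25.5"
      - "I42.0"
      - "I42.5–I42.9"
      - "143.x"
      - "150.x"
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
      - "I05.x–108.x"
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
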