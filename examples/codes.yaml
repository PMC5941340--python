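# Sample code-set configuration (mirrors the built-in default).
# Diagnostic entries are ICD prefixes (dots optional); treatment entries are
# exact billing-act / intervention codes. Real deployments replace the
# treatment lists with their jurisdiction's billing acts.
name: crc-example
icd9: ["153", "154.0", "154.1"]
icd10: ["C18", "C19", "C20"]
treatment:
  surgery: [SURG-COLECT, SURG-PROCT, SURG-LAR]
  chemo_radio: [CHEMO-FU, CHEMO-FOLFOX, RADIO-PELV]
  other: [OTH-STOMA, OTH-PALL]
site_map:
  "153": colon
  "C18": colon
  "154.0": rectum
  "154.1": rectum
  "C19": rectum
  "C20": rectum
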