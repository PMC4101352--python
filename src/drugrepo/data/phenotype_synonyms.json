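{
  "T2D": [
    "type 2 diabetes",
    "type II diabetes",
    "type 2 diabetes mellitus",
    "diabetes mellitus type 2",
    "non-insulin-dependent diabetes",
    "NIDDM",
    "diabetes mellitus"
  ],
  "T1D": [
    "type 1 diabetes",
    "type I diabetes",
    "type 1 diabetes mellitus",
    "diabetes mellitus type 1",
    "insulin-dependent diabetes",
    "juvenile diabetes",
    "IDDM",
    "diabetes mellitus"
  ],
  "RA": [
    "rheumatoid arthritis"
  ],
  "HT": [
    "hypertension",
    "high blood pressure",
    "hypertensive disease"
  ],
  "BD": [
    "bipolar disorder",
    "bipolar affective disorder",
    "manic depression",
    "manic-depressive illness"
  ],
  "CD": [
    "crohn's disease",
    "crohn disease",
    "crohns disease",
    "regional enteritis"
  ],
  "CAD": [
    "coronary artery disease",
    "coronary heart disease",
    "ischemic heart disease",
    "ischaemic heart disease",
    "myocardial infarction",
    "angina pectoris"
  ]
}
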