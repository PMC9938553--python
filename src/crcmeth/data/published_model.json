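{
  "intercept": 15.7174,
  "coefficients": {
    "cg13096260": -0.3146,
    "cg12993163": -0.2224
  },
  "provenance": "combined two-marker logistic diagnostic score fitted on the stool training cohort; frozen published coefficients",
  "frozen": true
}
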