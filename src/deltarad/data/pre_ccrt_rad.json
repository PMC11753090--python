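{
 "name": "Pre-CCRT_rad",
 "lambda": 0.019,
 "coefficients": {
  "GLDM Dependence Non-Uniformity Normalized": -0.210,
  "GLDM Dependence Variance": 0.583,
  "GLDM Gray Level Variance": -0.094,
  "GLRLM Long Run Emphasis": -0.270,
  "GLSZM Size Zone Non-Uniformity Normalized": 0.132,
  "GLSZM Small Area Emphasis": 0.142,
  "GLSZM Small Area High Gray Level Emphasis": 0.128
 }
}
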