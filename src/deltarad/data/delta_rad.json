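{
 "name": "Delta_rad",
 "lambda": 0.033,
 "coefficients": {
  "GLCM Autocorrelation": -0.020,
  "GLCM Inverse Variance": 0.006,
  "GLDM Dependence Variance": -0.379,
  "GLDM Gray Level Variance": 0.044,
  "GLSZM Size Zone Non-Uniformity Normalized": -0.239,
  "GLSZM Zone Percentage": -0.350
 }
}
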