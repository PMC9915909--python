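{
  "comment": "Published per-year variance contribution rates (percent) of the five-indicator correlation-matrix PCA for the Belt-and-Road study area, used to exercise the 80% component-selection rule.",
  "2010": [63.446, 22.217],
  "2015": [64.262, 20.183],
  "2020": [51.272, 24.486, 17.448],
  "published_cumulative": {
    "2010": [63.446, 85.663],
    "2015": [64.262, 84.445],
    "2020": [51.272, 75.758, 93.206]
  }
}
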