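{
  "description": "Published per-method candidate CpG mediator sets (FDR < 0.05) from the motivating cord-blood methylation mediation analysis of maternal exposures and standardized birth weight.",
  "GWG": {
    "HDMA": ["cg19242268", "cg08461903", "cg14798382", "cg21516291"],
    "HIMA": ["cg19242268", "cg08461903", "cg21516291"],
    "HIMA2": ["cg19242268", "cg08461903"]
  },
  "BMI": {
    "HDMA": ["cg17040807", "cg19242268", "cg26552621", "cg04457572", "cg06457011"],
    "HIMA": ["cg17040807", "cg19242268", "cg26552621", "cg04457572", "cg06457011"],
    "HIMA2": []
  }
}
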