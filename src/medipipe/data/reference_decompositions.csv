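exposure,model,component,chain,estimate,ci_low,ci_high,se,p
GWG,single_cg19242268,indirect,cg19242268,0.0026,0.0003,0.0066,,
GWG,single_cg19242268,direct,,0.0267,,,0.007,0.0001
GWG,single_cg19242268,total,,0.0293,,,0.007,0.00002
GWG,single_cg08461903,indirect,cg08461903,0.0019,-0.0006,0.0051,,
GWG,single_cg08461903,direct,,0.0260,,,0.007,0.0001
GWG,single_cg08461903,total,,0.0279,,,0.007,0.00004
GWG,single_cg14798382,indirect,cg14798382,0.0042,0.0012,0.0082,,
GWG,single_cg14798382,direct,,0.0240,,,0.007,0.0003
GWG,single_cg14798382,total,,0.0282,,,0.007,0.00004
GWG,single_cg21516291,indirect,cg21516291,0.0019,-0.0008,0.0054,,
GWG,single_cg21516291,direct,,0.0248,,,0.007,0.0002
GWG,single_cg21516291,total,,0.0267,,,0.007,0.00009
GWG,serial,indirect,cg19242268,0.00223,0.00025,0.00578,,
GWG,serial,indirect,cg08461903,0.00167,-0.00065,0.00462,,
GWG,serial,indirect,cg14798382,0.00267,0.00017,0.00624,,
GWG,serial,indirect,cg19242268|cg08461903,0.00010,-0.00006,0.00055,,
GWG,serial,indirect,cg19242268|cg14798382,0.00014,-0.00002,0.00062,,
GWG,serial,indirect,cg08461903|cg14798382,0.00021,-0.00005,0.00071,,
GWG,serial,indirect,cg19242268|cg08461903|cg14798382,0.00001,-0.00001,0.00009,,
GWG,serial,total_indirect,,0.00703,0.00267,0.01218,,
GWG,serial,direct,,0.01898,,,0.007,0.005
GWG,serial,total,,0.02601,,,0.007,0.0002
GWG,parallel,indirect,cg19242268,0.0022,0.0002,0.0058,,
GWG,parallel,indirect,cg08461903,0.0018,-0.0005,0.0048,,
GWG,parallel,indirect,cg14798382,0.0035,0.0010,0.0071,,
GWG,parallel,total_indirect,,0.0075,0.0032,0.0127,,
GWG,parallel,direct,,0.0190,,,0.007,0.005
GWG,parallel,total,,0.0265,,,0.007,0.0001
BMI,single_cg17040807,indirect,cg17040807,0.0033,-0.0001,0.0085,,
BMI,single_cg17040807,direct,,0.0308,,,0.009,0.001
BMI,single_cg17040807,total,,0.0341,,,0.009,0.0003
BMI,single_cg19242268,indirect,cg19242268,0.0037,0.0004,0.0084,,
BMI,single_cg19242268,direct,,0.0310,,,0.009,0.0006
BMI,single_cg19242268,total,,0.0347,,,0.009,0.0001
BMI,single_cg26552621,indirect,cg26552621,0.0051,0.0012,0.0107,,
BMI,single_cg26552621,direct,,0.0313,,,0.009,0.001
BMI,single_cg26552621,total,,0.0364,,,0.009,0.0001
BMI,single_cg04457572,indirect,cg04457572,0.0041,0.0006,0.0097,,
BMI,single_cg04457572,direct,,0.0327,,,0.009,0.0002
BMI,single_cg04457572,total,,0.0368,,,0.009,0.00007
BMI,single_cg06457011,indirect,cg06457011,0.0030,-0.0006,0.0078,,
BMI,single_cg06457011,direct,,0.0318,,,0.009,0.0006
BMI,single_cg06457011,total,,0.0348,,,0.009,0.0002
BMI,serial,indirect,cg19242268,0.002940,0.000405,0.007337,,
BMI,serial,indirect,cg26552621,0.002378,0.000245,0.006358,,
BMI,serial,indirect,cg04457572,0.002302,-0.000221,0.006550,,
BMI,serial,indirect,cg19242268|cg26552621,0.000439,0.000047,0.001313,,
BMI,serial,indirect,cg19242268|cg04457572,-0.000005,-0.000317,0.000271,,
BMI,serial,indirect,cg26552621|cg04457572,0.000903,0.000146,0.002294,,
BMI,serial,indirect,cg19242268|cg26552621|cg04457572,0.000167,0.000024,0.000482,,
BMI,serial,total_indirect,,0.009124,0.003671,0.016250,,
BMI,serial,direct,,0.026174,,,0.009,0.003
BMI,serial,total,,0.035298,,,0.009,0.0001
BMI,parallel,indirect,cg17040807,0.0015,-0.00009,0.0051,,
BMI,parallel,indirect,cg19242268,0.0027,0.0004,0.0068,,
BMI,parallel,indirect,cg26552621,0.0015,-0.0003,0.0052,,
BMI,parallel,indirect,cg04457572,0.0026,0.0004,0.0072,,
BMI,parallel,indirect,cg06457011,0.0019,-0.0001,0.0061,,
BMI,parallel,total_indirect,,0.0102,0.0041,0.0177,,
BMI,parallel,direct,,0.0232,,,0.009,0.009
BMI,parallel,total,,0.0334,,,0.009,0.0002
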