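diet,mei,thp,fhp,re,pd,ld,rq_fed,rq_fasted,de,me,ne,me_de,ne_me
T1,2066.73,1176.64,853.09,890.09,386.42,503.66,1.03,0.83,17.79,17.23,14.50,97.00,84.20
T2,2036.18,1150.69,854.36,885.49,279.48,606.01,1.03,0.81,18.15,17.68,15.13,97.20,85.60
T3,2018.06,1173.54,827.46,844.52,278.27,566.25,1.03,0.81,18.09,17.45,14.49,96.60,83.00
T4,2039.59,1168.28,823.37,871.31,281.00,590.30,1.04,0.81,18.38,17.72,14.78,96.40,83.40
T5,2027.80,1093.23,834.21,934.57,351.86,582.71,1.01,0.82,18.57,18.07,15.76,97.00,87.00
T6,2013.16,1112.11,847.62,901.05,518.03,383.02,1.01,0.83,18.66,17.69,15.43,94.80,87.40
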