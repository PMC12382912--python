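diet,dm,ash,ee,ndf,adf,cp,ge
T1,85.99,4.36,2.90,11.14,4.03,16.31,17.53
T2,85.91,4.18,2.05,7.83,2.70,12.35,17.09
T3,86.23,4.23,2.01,7.40,2.29,12.08,17.15
T4,85.83,4.13,2.03,7.28,2.47,12.19,17.22
T5,87.74,4.41,6.92,9.81,3.27,16.03,18.33
T6,85.09,4.23,2.50,9.67,3.07,23.58,17.84
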