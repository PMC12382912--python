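ingredient,T1,T2,T3,T4,T5,T6
Corn,72.90,51.44,51.44,51.44,68.75,64.39
Soybean meal,23.20,16.37,16.37,16.37,21.88,20.49
Corn starch,0.00,27.00,0.00,0.00,0.00,0.00
Pea starch,0.00,0.00,27.00,0.00,0.00,0.00
Tapioca starch,0.00,0.00,0.00,27.00,0.00,0.00
Soybean oil,0.00,0.00,0.00,0.00,5.00,0.00
Casein,0.00,0.00,0.00,0.00,0.00,11.80
Dicalcium phosphate,0.85,1.00,1.00,1.00,0.90,0.80
L-lysine-HCl,0.50,0.96,0.96,0.96,0.73,0.00
DL-methionine,0.09,0.23,0.23,0.23,0.12,0.05
L-threonine,0.10,0.25,0.25,0.25,0.13,0.01
L-tryptophan,0.04,0.08,0.08,0.08,0.05,0.04
L-valine,0.01,0.21,0.21,0.21,0.05,0.01
Salt,0.21,0.26,0.26,0.26,0.29,0.31
Limestone,1.10,1.20,1.20,1.20,1.10,1.10
Premix,1.00,1.00,1.00,1.00,1.00,1.00
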