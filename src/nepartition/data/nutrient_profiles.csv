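nutrient,dj,mj,pj,kj,ge,de,me,ne
Basal,0.87,0.97,0.19,0.81,18.36,16.02,15.52,14.50
Corn starch,0.99,0.99,0.05,0.88,16.13,16.03,15.77,15.06
Pea starch,0.99,0.95,0.05,0.80,16.30,16.06,15.37,14.37
Tapioca starch,1.00,0.95,0.05,0.86,17.02,17.07,16.34,15.22
Soybean oil,0.96,0.99,0.12,0.95,37.97,36.49,36.16,34.03
Casein,0.95,0.88,0.51,0.68,20.20,19.18,16.89,16.22
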