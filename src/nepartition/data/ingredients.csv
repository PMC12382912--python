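name,category,ge,cp,ee,starch,ndf,adf,ash,pd,ld
Peanut meal,protein,19.17,52.63,1.90,15.23,18.87,7.43,6.85,1339.02,456.01
Soybean meal,protein,19.17,52.97,0.88,3.50,15.00,6.68,7.07,1385.60,7.60
Soybean meal,protein,19.47,51.23,2.10,3.50,17.55,7.76,6.41,1361.60,5.95
Soybean meal,protein,19.29,50.25,1.28,3.50,19.73,9.17,6.56,1277.60,3.60
Soybean meal,protein,19.12,49.25,0.93,3.50,17.46,7.40,6.83,1337.60,35.60
Soybean meal,protein,19.50,48.52,1.20,0.00,17.08,9.96,6.21,1195.06,5.59
Soybean meal,protein,19.21,48.02,1.25,3.50,15.73,7.74,6.27,1321.60,15.60
Cottonseed meal,protein,17.99,46.43,0.27,1.80,33.02,15.35,6.28,1098.74,31.13
Rapeseed meal,protein,19.54,42.36,1.08,0.00,30.75,20.70,6.97,1530.06,115.59
Rapeseed meal,protein,19.37,41.83,1.68,2.26,39.83,24.79,9.14,730.25,98.34
Rapeseed meal,protein,19.60,41.03,1.71,3.12,30.84,20.04,7.22,694.35,75.26
Rapeseed meal,protein,19.47,39.92,2.58,3.02,37.27,21.50,8.24,637.94,98.34
Rapeseed cake,protein,20.56,39.75,6.55,4.43,32.34,21.75,6.94,689.22,31.67
Rapeseed cake,protein,21.33,39.23,9.52,0.00,36.98,22.84,6.41,815.06,0.00
Rapeseed meal,protein,18.11,38.23,1.02,3.58,25.88,15.64,6.54,750.02,26.01
Rapeseed cake,protein,21.35,37.70,11.27,2.95,41.00,24.18,7.49,196.91,642.69
Sunflower meal,protein,19.13,32.49,1.93,4.91,43.51,28.97,8.51,475.60,19.34
DDGS,protein,20.16,26.95,10.58,3.97,39.93,12.23,4.99,406.98,706.00
Corn gluten feed,protein,18.58,23.05,2.34,14.85,42.27,12.70,5.70,437.40,241.23
Corn germ meal,protein,19.31,21.53,2.07,19.54,50.30,14.38,1.85,342.26,453.53
Full-fat rice bran,protein,20.61,15.30,16.04,32.92,17.78,7.38,8.11,343.12,809.09
Corn,energy,18.84,8.71,4.06,74.19,10.22,1.35,1.51,193.08,1011.87
Corn,energy,18.79,8.77,3.74,74.19,10.85,2.32,1.67,206.40,904.02
Corn,energy,18.53,8.61,3.68,74.28,9.82,1.07,2.05,181.71,1006.61
Corn,energy,18.76,8.54,3.75,74.64,10.36,2.08,1.77,182.66,1002.06
Corn,energy,18.71,9.51,3.86,71.93,10.94,2.10,1.70,233.37,1016.11
Corn,energy,18.74,9.34,3.62,71.90,10.93,1.96,1.47,195.13,1027.26
Corn,energy,16.37,7.60,3.32,66.44,13.06,2.83,1.13,197.74,965.94
Corn,energy,16.02,8.31,2.16,61.03,7.21,1.58,1.06,112.75,76.43
Corn,energy,16.02,8.31,2.16,61.03,7.21,1.58,1.06,112.16,311.06
Corn,energy,16.02,8.31,2.16,61.03,7.21,1.58,1.06,360.91,540.67
Wheat,energy,16.48,13.76,1.59,60.78,12.38,3.15,1.67,350.26,761.66
Wheat,energy,16.19,14.51,1.76,50.85,13.30,2.31,1.78,367.67,712.84
Husked millet,energy,17.11,14.27,1.23,65.16,8.29,1.56,1.21,410.03,970.96
Millet,energy,17.49,12.17,1.88,51.34,22.74,11.07,2.34,330.46,733.66
Naked oat,energy,17.06,15.31,3.68,59.30,12.73,3.14,1.83,398.22,796.43
Sorghum,energy,16.42,10.13,2.79,61.66,11.37,3.78,1.55,210.80,828.66
Barley,energy,16.21,9.68,1.63,54.43,24.68,6.62,2.38,276.23,806.95
Unpolished rice,energy,15.88,9.99,1.56,70.81,10.26,1.68,1.15,276.45,974.32
Partially husked barley,energy,16.33,9.95,1.89,58.35,20.78,2.98,1.67,281.87,895.34
Soybean oil,lipid,0.00,0.35,93.65,0.00,0.00,0.00,3.24,8.12,2823.49
Soybean oil,lipid,0.00,0.35,94.65,0.00,1.13,0.00,0.00,65.08,3728.48
Poultry oil,lipid,0.00,0.00,91.40,0.00,0.00,0.00,3.20,6.77,3008.14
Linseed oil,lipid,0.00,0.00,91.00,0.00,0.00,0.00,2.70,7.66,3208.03
Fish oil,lipid,0.00,0.00,86.90,0.00,0.00,0.00,2.10,86.77,3158.47
Corn oil,lipid,0.00,0.00,88.30,0.00,0.00,0.00,3.20,6.77,3208.05
Palm oil,lipid,0.00,0.00,91.50,0.00,0.00,0.00,4.00,66.77,3158.11
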