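response,n_terms,intercept,ge,cp,ee,starch,ndf,adf,ash,r2,rmse,aic,bic,validation_r2
pd,1,-23.37,,23.50,,,,,,0.87,173.36,373.09,376.08,0.78
pd,2,37.56,,28.98,,,,-24.51,,0.96,105.45,346.89,350.48,0.77
pd,3,48.64,,29.64,,,,-23.77,-7.77,0.96,106.99,349.54,353.48,0.77
pd,4,364.36,-18.44,29.10,-3.79,,,-21.37,,0.96,105.15,350.66,354.65,0.80
pd,5,509.27,-17.47,26.61,-5.41,-2.01,,-24.37,,0.96,106.18,353.56,357.28,0.79
pd,6,640.63,-17.12,24.56,-6.88,-3.36,-2.49,-21.91,,0.96,108.06,357.21,360.29,0.80
pd,7,643.11,-18.60,24.54,-7.02,-3.13,-2.21,-22.21,3.45,0.96,110.66,361.60,363.59,0.80
ld,1,3106.14,-141.09,,,,,,,0.88,359.68,413.96,416.95,0.88
ld,2,1.25,,,35.15,11.46,,,,0.96,199.62,382.62,386.21,0.97
ld,3,-200.77,,,37.34,13.10,6.37,,,0.97,193.09,382.61,386.54,0.97
ld,4,-1276.12,,16.77,49.36,24.81,15.65,,,0.97,183.93,381.97,385.96,0.97
ld,5,-1503.50,,21.58,51.98,26.30,26.81,-23.87,,0.98,172.85,380.85,384.57,0.97
ld,6,-1424.08,-5.51,21.91,51.11,26.46,26.91,-22.82,,0.98,176.67,384.74,387.82,0.97
ld,7,-1413.85,-11.61,21.86,50.55,27.41,28.06,-24.06,14.23,0.98,180.37,388.96,390.95,0.97
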