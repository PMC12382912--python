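diet,bw,dm_intake,attd_ge,attd_om,attd_cp,attd_ee,attd_ndf,attd_adf,n_intake,fecal_n,urinary_n,n_retention,net_protein_availability
T1,30.66,935,87.28,87.19,86.90,54.75,54.87,48.13,28.38,3.71,4.44,20.22,0.71
T2,30.63,897,91.23,91.51,88.68,54.60,56.85,47.90,20.63,2.32,3.69,14.62,0.71
T3,29.69,884,90.97,91.27,87.74,53.70,55.60,43.94,19.83,2.43,3.12,14.27,0.72
T4,29.62,878,91.59,91.82,89.26,50.39,54.62,51.83,19.96,2.13,3.43,14.40,0.72
T5,30.64,874,88.89,88.91,86.26,79.47,56.15,45.99,25.57,3.52,3.68,18.37,0.72
T6,30.72,889,88.98,88.96,90.01,52.60,50.91,39.22,39.39,3.94,8.34,27.11,0.69
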