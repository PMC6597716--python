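table,enzyme,temperature_C,Km_IPM_uM,Km_IPM_err_uM,Km_IPM_rel_printed,Km_NAD_uM,Km_NAD_err_uM,Km_NAD_rel_printed,kcat_per_s,kcat_err_per_s,kcat_rel_printed
1,TtIPMDH,25,,,,2.2,0.3,1.0,0.37,0.01,1.0
1,mut#3,25,,,,19,5,8.6,1.1,0.1,3.0
1,mut#5,25,,,,200,40,91,1.3,0.1,3.5
1,mut#9,25,,,,27,1,12,3.5,0.0,9.5
1,mut#11,25,,,,74,8,34,2.9,0.1,7.8
1,mut#15,25,,,,150,20,68,0.55,0.03,1.5
1,mut#17,25,,,,16,4,7.3,0.66,0.04,1.8
1,mut#18,25,,,,7.0,0.7,3.2,0.36,0.00,0.97
1,mut#20,25,,,,92,24,42,0.66,0.06,1.8
1,mut#21,25,,,,8.6,1.5,3.9,0.70,0.02,1.9
1,mut#28,25,,,,560,70,250,3.3,0.2,8.9
1,EcIPMDH,25,,,,62,4,28,13,0.3,35
2,TtIPMDH,25,,,,2.2,0.3,1.0,0.37,0.01,1.0
2,mut9/17,25,,,,51,3,24,4.2,0.1,11
2,mut9/21,25,,,,100,10,48,4.3,0.1,12
2,EcIPMDH,25,,,,62,4,57,13,0,34
2,TtIPMDH,40,2.3,0.8,1.0,12,1,1.0,2.4,0.1,1.0
2,mut9/17,40,1.7,0.3,0.75,110,10,9.3,15,0,6.2
2,mut9/21,40,3.0,0.7,1.3,220,10,19,16,0,6.8
2,EcIPMDH,40,4.0,0.6,1.7,170,20,14,56,2,23
2,TtIPMDH,70,3.7,1.4,1.0,210,10,1.0,79,3,1.0
2,mut9/17,70,3.3,1.9,0.89,1200,100,5.9,80,2,1.0
2,mut9/21,70,3.6,1.8,0.96,1600,300,7.5,100,10,1.3
2,EcIPMDH,70,34,4,9.2,1200,100,6.0,190,10,2.3
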