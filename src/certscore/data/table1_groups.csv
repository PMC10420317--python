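group,variable,median,q25,q75
NW,age,29.15,26.46,33.14
NW,bmi,22.85,20.79,24.70
NW,wc,78.0,76.3,82.8
NW,sbp,120,110,120
NW,dbp,70,70,75
NW,glucose,87,82.25,94.25
NW,insulin,6.65,5.13,8.80
NW,homa_ir,1.54,1.07,1.84
NW,tc,173,158,200.50
NW,hdl,65,56.25,70.75
NW,ldl,106.50,86.25,120.50
NW,tg,63,53,85.75
NW,crp,0.10,0,0.20
NW,cer16,0.4463,0.3834,0.5280
NW,cer18,0.0663,0.0557,0.0790
NW,cer241,0.7663,0.5601,0.9362
NW,cer240,3.7086,2.9225,4.0040
NW,r16_240,0.1296,0.1116,0.1438
NW,r18_240,0.0187,0.0158,0.0241
NW,r241_240,0.2190,0.1928,0.2375
NW,frs,1.000,0.675,1.350
NW,va,16.000,13.750,18.000
OB-MetS-,age,27.38,21.35,35.65
OB-MetS-,bmi,42.88,40.75,119.25
OB-MetS-,wc,110.0,106.0,119.3
OB-MetS-,sbp,120,120,130
OB-MetS-,dbp,80,77.50,80
OB-MetS-,glucose,83,80,88.25
OB-MetS-,insulin,15.85,11,23.55
OB-MetS-,homa_ir,3.23,2.23,4.68
OB-MetS-,tc,160.50,133.25,188.50
OB-MetS-,hdl,45.50,39.50,50.25
OB-MetS-,ldl,101.50,77.75,122.25
OB-MetS-,tg,96,85.75,123.25
OB-MetS-,crp,0.50,0.28,1.03
OB-MetS-,cer16,0.4359,0.4025,0.4727
OB-MetS-,cer18,0.1121,0.0794,0.1377
OB-MetS-,cer241,0.9581,0.8408,1.1890
OB-MetS-,cer240,2.1955,1.7563,3.1066
OB-MetS-,r16_240,0.1896,0.1520,0.2371
OB-MetS-,r18_240,0.0454,0.0355,0.0655
OB-MetS-,r241_240,0.4044,0.3280,0.5424
OB-MetS-,frs,1.150,0.600,1.675
OB-MetS-,va,16.000,13.250,19.750
OB-MetS+,age,30.43,23.98,41.18
OB-MetS+,bmi,43.44,41.53,46.54
OB-MetS+,wc,120.0,113.3,126.5
OB-MetS+,sbp,130,130,140
OB-MetS+,dbp,80,80,90
OB-MetS+,glucose,86,82.25,94.75
OB-MetS+,insulin,25.05,19.08,30.25
OB-MetS+,homa_ir,5.30,4.32,6.21
OB-MetS+,tc,163,148,196
OB-MetS+,hdl,37.50,32.50,43.75
OB-MetS+,ldl,107.50,96,124.75
OB-MetS+,tg,125.50,103.50,159.25
OB-MetS+,crp,0.55,0.40,1.08
OB-MetS+,cer16,0.4533,0.3815,0.5484
OB-MetS+,cer18,0.1242,0.1053,0.1714
OB-MetS+,cer241,1.1021,0.8999,1.3634
OB-MetS+,cer240,2.3265,1.9734,3.0387
OB-MetS+,r16_240,0.1859,0.1706,0.2285
OB-MetS+,r18_240,0.0557,0.0480,0.0654
OB-MetS+,r241_240,0.4660,0.4076,0.5187
OB-MetS+,frs,2.450,1.100,4.325
OB-MetS+,va,23.500,17.750,30.000
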