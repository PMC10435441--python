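wavelength_nm,mu_a_oxy_per_mm,mu_a_deoxy_per_mm
450,33.6,55.3
475,16.0,15.0
500,11.2,11.2
520,13.0,17.0
540,28.7,25.0
550,26.7,29.0
560,17.7,28.7
570,24.0,24.3
575,29.7,21.4
580,26.0,19.9
590,10.0,16.0
600,1.71,7.86
610,0.56,5.57
620,0.31,4.01
635,0.22,2.70
650,0.19,2.01
670,0.17,1.35
700,0.15,0.96
730,0.21,0.60
750,0.28,0.75
775,0.36,0.65
800,0.44,0.41
825,0.51,0.38
850,0.57,0.39
880,0.62,0.43
900,0.64,0.43
940,0.65,0.37
970,0.64,0.32
1000,0.63,0.29
1100,0.52,0.26
1200,0.46,0.28
1300,0.40,0.30
1400,0.40,0.35
1500,0.38,0.37
1600,0.37,0.37
1750,0.36,0.36
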