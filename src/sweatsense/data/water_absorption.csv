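wavelength_nm,mu_a_per_mm
450,0.000026
475,0.000025
500,0.000025
525,0.000032
550,0.000045
575,0.000096
600,0.00023
620,0.00028
650,0.00034
680,0.00050
700,0.00062
720,0.00115
740,0.00235
750,0.00261
760,0.00248
780,0.00221
800,0.00206
820,0.00288
840,0.00397
860,0.00473
880,0.00553
900,0.00679
920,0.0109
940,0.0267
950,0.0320
960,0.0390
970,0.0450
975,0.0475
980,0.0466
990,0.0420
1000,0.0363
1020,0.0250
1040,0.0170
1060,0.0130
1080,0.0120
1100,0.0170
1130,0.0500
1150,0.0730
1160,0.0900
1180,0.1000
1200,0.1040
1220,0.1000
1240,0.0920
1260,0.0850
1280,0.0900
1300,0.1150
1320,0.1700
1340,0.2600
1360,0.4200
1380,0.8000
1400,1.2400
1420,1.8500
1440,2.6500
1450,2.8900
1460,2.9500
1470,2.8000
1480,2.5100
1500,2.0600
1520,1.6000
1540,1.2600
1560,1.0100
1580,0.8500
1600,0.6900
1620,0.6000
1640,0.5400
1660,0.5000
1680,0.4800
1700,0.5000
1720,0.5500
1750,0.6500
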