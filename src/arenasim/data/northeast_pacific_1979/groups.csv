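name,role,B,PB,QB,EE,BA,E,UN,pedigree
TKW,consumer,0.000046,0.044,11.08,,0,0,0.15,**
SRKW,consumer,0.00084,0.05208,10.17,,0.005,0,0.15,**
NRKW,consumer,0.0017,0.0416,10.17,,0.023,0,0.15,**
Porpoises/dolphins,consumer,0.0125,0.3,38.37,,0,0,0.15,***
Harbor seals,consumer,0.00863,0.212,15.5,,0.012,0,0.15,**
Steller sea lions,consumer,0.0053,0.162,24.45,,0.048,0,0.15,**
California sea lions,consumer,0.0229,0.144,16.89,,0.054,0,0.15,**
Seabirds,consumer,0.0058,0.1375,93.7,,0,0,0.15,**
FRGSPS SP River,consumer,0.000377762,0.5,8.98533,,0,0,0.2,
FRGSPS SP Smolts,consumer,0.000449512,3.5,5.771215,,0,0,0.2,
FRGSPS SP Juveniles,consumer,0.000933173,0.8,4.058203,,0,0,0.2,
FRGSPS SP Marine,consumer,0.002487325,0.44,2.834945,,0,0,0.2,
FRGSPS SP Returning spawners,consumer,0.006,0.72,2,,0,0,0.2,
FRGSPS SP Escapees,consumer,0.05373438,0.157,1.050405,,0,0,0.2,
FRGSPS SU River,consumer,1.17e-05,1,39.86551,,0,0,0.2,
FRGSPS SU Smolts,consumer,0.00090348,3.5,10.44263,,0,0,0.2,
FRGSPS SU Juveniles,consumer,0.003396815,0.510826,4.300026,,0,0,0.2,
FRGSPS SU Marine,consumer,0.007634544,0.55,2.813696,,0,0,0.2,
FRGSPS SU Returning spawners,consumer,0.015,0.89,2,,0,0,0.2,
FRGSPS SU Escapees,consumer,0.1190069,0.15,1.031226,,0,0,0.2,
FRGSPS FA River,consumer,3.28e-05,1,39.59757,,0,0,0.2,
FRGSPS FA Smolts,consumer,0.003113446,3,10.03799,,0,0,0.2,
FRGSPS FA Juveniles,consumer,0.01393653,0.5,4.268976,,0,0,0.2,
FRGSPS FA Marine,consumer,0.03764028,0.2,2.767977,,0,0,0.2,
FRGSPS FA Returning spawners,consumer,0.08,1,2,,0,0,0.2,
FRGSPS FA Escapees,consumer,0.1849568,0.31,1.172155,,0,0,0.2,
WCVI FA River,consumer,1.35e-05,1,39.59756,,0,0,0.2,
WCVI FA Smolts,consumer,0.000854519,4,10.73029,,0,0,0.2,
WCVI FA Juveniles,consumer,0.00269063,0.510826,4.271125,,0,0,0.2,
WCVI FA Marine,consumer,0.005812909,0.63,2.801022,,0,0,0.2,
WCVI FA Returning spawners,consumer,0.01,1,2,,0,0,0.2,
WCVI FA Escapees,consumer,0.0451843,0.2,1.078224,,0,0,0.2,
CRWORC SP River,consumer,0.000372801,1,9.076533,,0,0,0.2,
CRWORC SP Smolts,consumer,0.00046814,2,5.612062,,0,0,0.2,
CRWORC SP Juveniles,consumer,0.00146552,0.510826,3.966077,,0,0,0.2,
CRWORC SP Marine,consumer,0.004267717,0.459,2.787735,,0,0,0.2,
CRWORC SP Returning spawners,consumer,0.008,1,2,,0,0,0.2,
CRWORC SP Escapees,consumer,0.05267467,0.156,1.031227,,0,0,0.2,
CRWORC SU River,consumer,0.002606931,1,9.132318,,0,0,0.2,
CRWORC SU Smolts,consumer,0.003273621,2,5.646552,,0,0,0.2,
CRWORC SU Juveniles,consumer,0.0102851,0.5,3.989615,,0,0,0.2,
CRWORC SU Marine,consumer,0.03097257,0.4,2.800298,,0,0,0.2,
CRWORC SU Returning spawners,consumer,0.065,0.9,2,,0,0,0.2,
CRWORC SU Escapees,consumer,0.6308022,0.13,1.006305,,0,0,0.2,
CRWORC FA River,consumer,2.88e-05,1,40.11358,,0,0,0.2,
CRWORC FA Smolts,consumer,0.003395708,2.5,9.854838,,0,0,0.2,
CRWORC FA Juveniles,consumer,0.01772177,0.510826,4.326784,,0,0,0.2,
CRWORC FA Marine,consumer,0.03996976,0.543,2.830654,,0,0,0.2,
CRWORC FA Returning spawners,consumer,0.086,0.79,2,,0,0,0.2,
CRWORC FA Escapees,consumer,0.09529229,0.6,1.339623,,0,0,0.2,
Coho River,consumer,0.007927025,1,25.67039,,0,0,0.2,
Coho Smolts,consumer,0.01462168,2,15.10733,,0,0,0.2,
Coho Marine,consumer,0.08549532,0.4,8.861984,,0,0,0.2,
Coho Returning spawners,consumer,0.079,0.8,6.489996,,0,0,0.2,
Coho Escapees,consumer,0.1448364,0.8,4.902339,,0,0,0.2,
Chum River,consumer,0.000256017,1,22.30038,,0,0,0.2,
Chum Smolts,consumer,0.04662696,2.5,4.732551,,0,0,0.2,
Chum Marine,consumer,0.1130326,1,2.071343,,0,0,0.2,
Chum Returning spawners,consumer,0.07,1.2,1.4,,0,0,0.2,
Chum Escapees,consumer,0.05169914,0.4,1.023608,,0,0,0.2,
Herring Juveniles,consumer,0.6268337,0.5,8.277314,,0,0,0.2,
Herring Adults,consumer,2.7,1,4,,0,0,0.2,
Other salmonids,consumer,1.57,1.34,3.8,,0,0,0.2,
Halibut,consumer,0.11,0.2065,1.85,,0,0,0.2,
Hake,consumer,4.02,0.3,1.85,,0,0,0.2,
Rockfish,consumer,1,0.365,3.11,,0,0,0.2,
Lingcod,consumer,0.05,0.54,1.7,,0,0,0.2,
Pacific sand lance,consumer,2,0.77,7.3,,0,0,0.2,
Other forage fish,consumer,10,0.77,38.4,,0,0,0.2,****
Other fish,consumer,40,0.5,2.5,,0,0,0.2,****
Invertebrates,consumer,50,3.05,11.1,,0,0,0.2,
Zooplankton,consumer,50,17,50,,0,0,0.2,
Phytoplankton,producer,31,130,,,0,0,0.2,
Detritus,detritus,10,,,,0,0,0,
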