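species,stanza,start_month,end_month,Z,leading,vbK,wmat_over_winf,rec_power,terminal
FRGSPS SP,FRGSPS SP River,0,12,0.5,False,0.9,0.5,1.0,True
FRGSPS SP,FRGSPS SP Smolts,12,24,3.5,False,0.9,0.5,1.0,True
FRGSPS SP,FRGSPS SP Juveniles,24,36,0.8,False,0.9,0.5,1.0,True
FRGSPS SP,FRGSPS SP Marine,36,48,0.44,False,0.9,0.5,1.0,True
FRGSPS SP,FRGSPS SP Returning spawners,48,60,0.72,True,0.9,0.5,1.0,True
FRGSPS SP,FRGSPS SP Escapees,60,72,0.157,False,0.9,0.5,1.0,True
FRGSPS SU,FRGSPS SU River,0,12,1,False,0.9,0.5,1.0,True
FRGSPS SU,FRGSPS SU Smolts,12,24,3.5,False,0.9,0.5,1.0,True
FRGSPS SU,FRGSPS SU Juveniles,24,36,0.510826,False,0.9,0.5,1.0,True
FRGSPS SU,FRGSPS SU Marine,36,48,0.55,False,0.9,0.5,1.0,True
FRGSPS SU,FRGSPS SU Returning spawners,48,60,0.89,True,0.9,0.5,1.0,True
FRGSPS SU,FRGSPS SU Escapees,60,72,0.15,False,0.9,0.5,1.0,True
FRGSPS FA,FRGSPS FA River,0,12,1,False,0.9,0.5,1.0,True
FRGSPS FA,FRGSPS FA Smolts,12,24,3,False,0.9,0.5,1.0,True
FRGSPS FA,FRGSPS FA Juveniles,24,36,0.5,False,0.9,0.5,1.0,True
FRGSPS FA,FRGSPS FA Marine,36,48,0.2,False,0.9,0.5,1.0,True
FRGSPS FA,FRGSPS FA Returning spawners,48,60,1,True,0.9,0.5,1.0,True
FRGSPS FA,FRGSPS FA Escapees,60,72,0.31,False,0.9,0.5,1.0,True
WCVI FA,WCVI FA River,0,12,1,False,0.9,0.5,1.0,True
WCVI FA,WCVI FA Smolts,12,24,4,False,0.9,0.5,1.0,True
WCVI FA,WCVI FA Juveniles,24,36,0.510826,False,0.9,0.5,1.0,True
WCVI FA,WCVI FA Marine,36,48,0.63,False,0.9,0.5,1.0,True
WCVI FA,WCVI FA Returning spawners,48,60,1,True,0.9,0.5,1.0,True
WCVI FA,WCVI FA Escapees,60,72,0.2,False,0.9,0.5,1.0,True
CRWORC SP,CRWORC SP River,0,12,1,False,0.9,0.5,1.0,True
CRWORC SP,CRWORC SP Smolts,12,24,2,False,0.9,0.5,1.0,True
CRWORC SP,CRWORC SP Juveniles,24,36,0.510826,False,0.9,0.5,1.0,True
CRWORC SP,CRWORC SP Marine,36,48,0.459,False,0.9,0.5,1.0,True
CRWORC SP,CRWORC SP Returning spawners,48,60,1,True,0.9,0.5,1.0,True
CRWORC SP,CRWORC SP Escapees,60,72,0.156,False,0.9,0.5,1.0,True
CRWORC SU,CRWORC SU River,0,12,1,False,0.9,0.5,1.0,True
CRWORC SU,CRWORC SU Smolts,12,24,2,False,0.9,0.5,1.0,True
CRWORC SU,CRWORC SU Juveniles,24,36,0.5,False,0.9,0.5,1.0,True
CRWORC SU,CRWORC SU Marine,36,48,0.4,False,0.9,0.5,1.0,True
CRWORC SU,CRWORC SU Returning spawners,48,60,0.9,True,0.9,0.5,1.0,True
CRWORC SU,CRWORC SU Escapees,60,72,0.13,False,0.9,0.5,1.0,True
CRWORC FA,CRWORC FA River,0,12,1,False,0.9,0.5,1.0,True
CRWORC FA,CRWORC FA Smolts,12,24,2.5,False,0.9,0.5,1.0,True
CRWORC FA,CRWORC FA Juveniles,24,36,0.510826,False,0.9,0.5,1.0,True
CRWORC FA,CRWORC FA Marine,36,48,0.543,False,0.9,0.5,1.0,True
CRWORC FA,CRWORC FA Returning spawners,48,60,0.79,True,0.9,0.5,1.0,True
CRWORC FA,CRWORC FA Escapees,60,72,0.6,False,0.9,0.5,1.0,True
Coho,Coho River,0,12,1,False,0.9,0.5,1.0,True
Coho,Coho Smolts,12,24,2,False,0.9,0.5,1.0,True
Coho,Coho Marine,24,36,0.4,False,0.9,0.5,1.0,True
Coho,Coho Returning spawners,36,48,0.8,True,0.9,0.5,1.0,True
Coho,Coho Escapees,48,60,0.8,False,0.9,0.5,1.0,True
Chum,Chum River,0,12,1,False,0.8,0.5,1.0,True
Chum,Chum Smolts,12,24,2.5,False,0.8,0.5,1.0,True
Chum,Chum Marine,24,36,1,False,0.8,0.5,1.0,True
Chum,Chum Returning spawners,36,48,1.2,True,0.8,0.5,1.0,True
Chum,Chum Escapees,48,60,0.4,False,0.8,0.5,1.0,True
Herring,Herring Juveniles,0,48,0.5,False,0.45,0.3,1.0,False
Herring,Herring Adults,48,,1,True,0.45,0.3,1.0,False
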