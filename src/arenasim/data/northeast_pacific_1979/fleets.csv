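fleet,group,landings
Combined fisheries,FRGSPS SP Marine,3.11e-05
Combined fisheries,FRGSPS SP Returning spawners,0.003074
Combined fisheries,FRGSPS SP Escapees,0.002929
Combined fisheries,FRGSPS SU Marine,0.000938
Combined fisheries,FRGSPS SU Returning spawners,0.010379
Combined fisheries,FRGSPS SU Escapees,0.005724
Combined fisheries,FRGSPS FA Marine,0.000903
Combined fisheries,FRGSPS FA Returning spawners,0.064264
Combined fisheries,FRGSPS FA Escapees,0.03246
Combined fisheries,WCVI FA Marine,0.001227
Combined fisheries,WCVI FA Returning spawners,0.005365
Combined fisheries,WCVI FA Escapees,0.004189
Combined fisheries,CRWORC SP Marine,0.000299
Combined fisheries,CRWORC SP Returning spawners,0.004551
Combined fisheries,CRWORC SP Escapees,0.002829
Combined fisheries,CRWORC SU Marine,0.004584
Combined fisheries,CRWORC SU Returning spawners,0.051773
Combined fisheries,CRWORC SU Escapees,0.018924
Combined fisheries,CRWORC FA Marine,0.005156
Combined fisheries,CRWORC FA Returning spawners,0.0516
Combined fisheries,CRWORC FA Escapees,0.034019
Combined fisheries,Coho Marine,0.0179
Combined fisheries,Coho Returning spawners,0.0166
Combined fisheries,Chum Returning spawners,0.012
Combined fisheries,Herring Adults,0.691
Combined fisheries,Other salmonids,0.366
Combined fisheries,Halibut,0.0139
Combined fisheries,Hake,0.329
Combined fisheries,Lingcod,0.0121
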