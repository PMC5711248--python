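# Reference cohort: lowest mean parotid dose (Gy) achieved per patient by the
# automated sparing strategy, IMRT vs VMAT, with TNM stage and the per-case
# difference column as printed in the source report.  Note: the printed delta
# for P9 (5.9) differs from the exact column difference (19.1 - 13.1 = 6.0);
# printed values are transcribed verbatim, not corrected.
patient,stage,imrt_gy,vmat_gy,delta_printed
P1,T3N2,19.4,19.1,0.3
P2,T1N2,18.3,16.7,1.6
P3,T2N3,13.9,13.8,0.1
P4,T2N1,25.0,23.8,1.2
P5,T2N1,20.6,15.5,5.0
P6,T3N1,18.8,17.2,1.6
P7,T2N2,23.4,21.5,1.9
P8,T3N2,20.5,15.6,4.9
P9,T2N1,19.1,13.1,5.9
P10,T3N1,16.7,13.9,2.7
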