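# Reference cohort: highest prescription dose (Gy, 2 Gy steps from 70 Gy, to
# the mean of CTV1) reached per patient by the isotoxic escalation strategy,
# IMRT vs VMAT, with nodal laterality subgroup (unilateral/bilateral neck
# nodes) and the printed per-case difference column.  Note: the source's
# quoted IMRT standard deviation (8.2) does not recompute from this column
# (sample SD is ~9.9); values are transcribed verbatim, not corrected.
patient,stage,laterality,imrt_gy,vmat_gy,delta_printed
P1,T3N2,bilateral,94.0,96.0,-2.0
P2,T1N2,bilateral,88.0,86.0,2.0
P3,T2N3,unilateral,102.0,84.0,18.0
P4,T2N1,bilateral,82.0,88.0,-6.0
P5,T1N1,unilateral,86.0,96.0,-10.0
P6,T3N1,unilateral,76.0,86.0,-10.0
P7,T2N2,unilateral,88.0,84.0,4.0
P8,T3N2,bilateral,92.0,92.0,0.0
P9,T2N1,bilateral,98.0,98.0,0.0
P10,T3N1,unilateral,110.0,98.0,12.0
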