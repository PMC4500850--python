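#element	mass_number	exact_mass
# Exact masses for isotopes commonly used in labelling; atoms carrying an
# explicit mass number outside this table fall back to the mass number.
H	1	1.00782503207
H	2	2.01410177785
H	3	3.01604927767
C	12	12.0
C	13	13.0033548378
C	14	14.0032419887
N	14	14.0030740048
N	15	15.0001088982
O	16	15.99491461956
O	17	16.99913170
O	18	17.9991610
F	18	18.0009380
S	34	33.96786690
Cl	37	36.96590259
Br	81	80.9162906
I	131	130.9061246
P	32	31.97390727
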