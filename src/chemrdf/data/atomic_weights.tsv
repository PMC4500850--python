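#element	standard_atomic_weight	principal_isotope_mass
# Standard atomic weights: IUPAC 2005/2007 tables (pinned; later revisions
# shift the 4th decimal for C, S, Zn and others).
# Principal-isotope masses: most abundant isotope, AME-derived values.
H	1.00794	1.00782503207
B	10.811	11.0093054
C	12.0107	12.0
N	14.0067	14.0030740048
O	15.9994	15.99491461956
F	18.9984032	18.99840322
Na	22.98976928	22.9897692809
Mg	24.3050	23.9850417
Al	26.9815386	26.98153863
Si	28.0855	27.97692653
P	30.973762	30.97376163
S	32.065	31.97207100
Cl	35.453	34.96885268
K	39.0983	38.96370668
Ca	40.078	39.96259098
Mn	54.938045	54.9380451
Fe	55.845	55.9349375
Cu	63.546	62.9295975
Zn	65.38	63.9291422
Se	78.96	79.9165213
Br	79.904	78.9183371
I	126.90447	126.904473
Li	6.941	7.01600455
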