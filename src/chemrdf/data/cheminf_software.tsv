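#name	version	cheminf_id
PubChem	2.1	CHEMINF_000333
OEChem	1.9.0	CHEMINF_000429
LexiChem	2.2.0	CHEMINF_000384
Cactvs	3.408	CHEMINF_000386
XLogP3	3.0	CHEMINF_000394
InChI	1.0.4	CHEMINF_000398
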