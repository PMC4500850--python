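#label	cheminf_id
ChEMBL identifier	CHEMINF_000412
KEGG identifier	CHEMINF_000409
Human Metabolome Database identifier	CHEMINF_000408
ChemSpider identifier	CHEMINF_000405
ChEBI identifier	CHEMINF_000407
DrugBank identifier	CHEMINF_000406
CAS registry number	CHEMINF_000446
EC number	CHEMINF_000447
RTECS number	CHEMINF_000566
LipidMaps identifier	CHEMINF_000564
National service center number	CHEMINF_000565
Unique ingredient identifier	CHEMINF_000563
Validated chemical database identifier	CHEMINF_000467
Drug trade name	CHEMINF_000561
International nonproprietary name	CHEMINF_000562
PubChem depositor-supplied name	CHEMINF_000339
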