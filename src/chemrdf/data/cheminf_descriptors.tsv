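#label	cheminf_id	software	datatype	unit
Molecular_Weight	CHEMINF_000334	PubChem	double	UO_0000055
Molecular_Formula	CHEMINF_000335	PubChem	string
Total_Formal_Charge	CHEMINF_000336	PubChem	integer
Mono_Isotopic_Weight	CHEMINF_000337	PubChem	double	UO_0000055
Exact_Mass	CHEMINF_000338	PubChem	double	UO_0000055
Compound_Identifier	CHEMINF_000140	PubChem	string
Covalent_Unit_Count	CHEMINF_000369	PubChem	nonNegativeInteger
Defined_Atom_Stereocenter_Count	CHEMINF_000370	PubChem	nonNegativeInteger
Defined_Bond_Stereocenter_Count	CHEMINF_000371	PubChem	nonNegativeInteger
Isotope_Atom_Count	CHEMINF_000372	PubChem	nonNegativeInteger
Heavy_Atom_Count	CHEMINF_000373	PubChem	nonNegativeInteger
Undefined_Atom_Stereocenter_Count	CHEMINF_000374	PubChem	nonNegativeInteger
Undefined_Bond_Stereocenter_Count	CHEMINF_000375	PubChem	nonNegativeInteger
Canonical_SMILES	CHEMINF_000376	OEChem	string
Isomeric_SMILES	CHEMINF_000379	OEChem	string
Preferred_IUPAC_Name	CHEMINF_000382	LexiChem	string
Hydrogen_Bond_Donor_Count	CHEMINF_000387	Cactvs	nonNegativeInteger
Hydrogen_Bond_Acceptor_Count	CHEMINF_000388	Cactvs	nonNegativeInteger
Rotatable_Bond_Count	CHEMINF_000389	Cactvs	nonNegativeInteger
Structure_Complexity	CHEMINF_000390	Cactvs	double
Tautomer_Count	CHEMINF_000391	Cactvs	nonNegativeInteger
TPSA	CHEMINF_000392	Cactvs	double
XLogP3	CHEMINF_000395	XLogP3	double
IUPAC_InChI	CHEMINF_000396	InChI	string
IUPAC_InChIKey	CHEMINF_000399	InChI	string
Substance_Version	-	PubChem	nonNegativeInteger
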