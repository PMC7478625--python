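# Single-copy marker set for concatenated phylogenomics: 18 universal
# ribosomal/translation proteins with curated equivalog HMMs.
# columns: accession<TAB>protein
TIGR02013	RpoB
TIGR00168	InfC
TIGR01953	NusA
TIGR01169	RplA
TIGR01171	RplB
TIGR03953	RplD
TIGR01066	RplM
TIGR01067	RplN
TIGR01164	RplP
TIGR01024	RplS
TIGR01032	RplT
TIGR01011	RpsB
TIGR01009	RpsC
TIGR01021	RpsE
TIGR01049	RpsJ
TIGR01050	RpsS
TIGR00086	SmpB
TIGR00116	Tsf
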