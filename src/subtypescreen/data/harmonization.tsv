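taxonomy	raw_label	harmonized
Lund	Ba/Sq	basal
Lund	GU	luminal
Lund	GU-inf	luminal
Lund	UroA	luminal
Lund	UroA-Prog	luminal
Lund	Mes-like	mesenchymal-like
Lund	Sc/NE-like	neuronal
Lund	Scc/NE-like	neuronal
MDA	basal	basal
MDA	luminal	luminal
MDA	p53-like	mesenchymal-like
TCGA	basal-squamous	basal
TCGA	luminal-papillary	luminal
TCGA	luminal	luminal
TCGA	luminal-infiltrated	mesenchymal-like
TCGA	neuronal	neuronal
Consensus	Ba/Sq	basal
Consensus	LumP	luminal
Consensus	LumU	luminal
Consensus	LumNS	luminal
Consensus	stroma-rich	mesenchymal-like
Consensus	NE-like	neuronal
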