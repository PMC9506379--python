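# Default mesenchymal / EMT marker gene list used for the mesenchymal-like
# fallback signature score. Editable: replace with any gene list, one symbol
# per line; lines starting with '#' are ignored.
VIM
ZEB1
ZEB2
SNAI1
SNAI2
TWIST1
TWIST2
CDH2
FN1
FOXC2
MMP2
MMP9
ITGAV
ITGB5
ITGB1
TGFB1
TGFBR2
SPARC
COL1A1
COL5A2
ACTA2
TAGLN
CNN1
MYL9
PDGFRB
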