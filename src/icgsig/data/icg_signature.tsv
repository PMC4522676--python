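gene_symbol	weight
CACNA1D	-1
CLCN6	-1
CLIC1	1
CLIC4	1
GLRB	-1
GRIA2	-1
GRID1	-1
KCNAB1	-1
KCNB1	-1
KCND2	-1
KCNJ10	-1
KCNMA1	-1
KCNN3	-1
KCNQ5	-1
NALCN	-1
P2RX7	-1
SCN1A	-1
VDAC2	-1
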